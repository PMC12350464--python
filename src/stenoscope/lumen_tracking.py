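"""Dark-region segmentation, IoU tracking and measurement-keyframe selection.

Under co-located illumination the airway lumen is the darkest image region,
so it is segmented with a plain intensity threshold on the grayscale frame
and tracked along the sequence with an intersection-over-union tracker that
tolerates a bounded run of transient failures.  When the tracker loses the
segment for longer than its patience — the darkest region has changed
shape or place for good, i.e. the camera has passed the vocal cords and now
faces the stenosis — the first frame of that terminal miss run is selected
as the measurement keyframe.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from skimage import measure

__all__ = [
    "LumenSegment",
    "TrackerConfig",
    "KeyframeResult",
    "TrackRecord",
    "to_grayscale",
    "segment_dark_region",
    "iou",
    "track_sequence",
    "load_frames",
    "write_track_log",
]


@dataclass(frozen=True)
class LumenSegment:
    """Largest dark connected component of one frame."""

    frame_index: int
    mask: np.ndarray            # boolean (H, W)
    area_px: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    centroid: tuple[float, float]    # (row, col)


@dataclass(frozen=True)
class TrackerConfig:
    """Defaults follow clinically validated values: intensity threshold 50
    (8-bit), minimum IoU 50%, 25 frames of patience."""

    intensity_threshold: int = 50
    min_iou: float = 0.50
    patience_frames: int = 25
    min_area_fraction: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.intensity_threshold < 255):
            raise ValueError("intensity_threshold must be in (0, 255)")
        if not (0 < self.min_iou <= 1):
            raise ValueError("min_iou must be in (0, 1]")
        if self.patience_frames < 0:
            raise ValueError("patience_frames must be >= 0")


class LossReason(str, Enum):
    tracking_lost = "tracking_lost"
    sequence_end_no_loss = "sequence_end_no_loss"
    never_initialized = "never_initialized"


@dataclass
class TrackRecord:
    frame_index: int
    segment_area: int
    iou: float
    miss_count: int
    state: str  # "init" | "tracked" | "miss" | "lost"


@dataclass
class KeyframeResult:
    keyframe_index: int | None
    loss_start_index: int | None
    reason: LossReason
    track_history: list[TrackRecord] = field(default_factory=list)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luma (weights 0.299, 0.587, 0.114), rounded half-up to uint8.

    Single-channel input passes through unchanged.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected 1- or 3-channel image, got shape {img.shape}")
    luma = (0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2])
    return np.floor(luma + 0.5).astype(np.uint8)


def segment_dark_region(gray: np.ndarray, config: TrackerConfig,
                        frame_index: int = 0) -> LumenSegment | None:
    """Largest 8-connected component of pixels below the intensity threshold.

    Returns ``None`` when no component reaches ``min_area_fraction`` of the
    frame area (absence of a dark region is a valid outcome, not an error).
    Components touching the image border are eligible.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    binary = gray < config.intensity_threshold
    if not binary.any():
        return None
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    area = int(counts[best])
    if area < config.min_area_fraction * gray.size:
        return None
    mask = labels == best
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    centroid = (float(rows.mean()), float(cols.mean()))
    return LumenSegment(frame_index=frame_index, mask=mask, area_px=area,
                        bbox=bbox, centroid=centroid)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two same-shape binary masks (0 when both
    are empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def track_sequence(frames: np.ndarray | list[np.ndarray],
                   config: TrackerConfig | None = None) -> KeyframeResult:
    """Track the largest dark segment and select the measurement keyframe.

    The tracker initializes on the first frame with a valid segment.  Each
    later frame's largest dark segment is compared (IoU) against the last
    successfully tracked mask; a match updates the reference, a mismatch
    (or an absent segment) increments a miss counter without touching the
    reference.  Once the misses exceed the patience, tracking is lost and
    the keyframe is the *first* frame of that terminal miss run — the frame
    where the darkest segment first changed, i.e. the camera has just
    reached the subglottis.
    """
    config = config or TrackerConfig()
    if len(frames) == 0:
        raise ValueError("need at least one frame")

    reference: LumenSegment | None = None
    miss_count = 0
    miss_start: int | None = None
    history: list[TrackRecord] = []

    for i, frame in enumerate(frames):
        gray = to_grayscale(np.asarray(frame))
        seg = segment_dark_region(gray, config, frame_index=i)
        if reference is None:
            if seg is not None:
                reference = seg
                history.append(TrackRecord(i, seg.area_px, 1.0, 0, "init"))
            else:
                history.append(TrackRecord(i, 0, 0.0, 0, "no_segment"))
            continue

        score = iou(seg.mask, reference.mask) if seg is not None else 0.0
        area = seg.area_px if seg is not None else 0
        if seg is not None and score >= config.min_iou:
            reference = seg
            miss_count = 0
            miss_start = None
            history.append(TrackRecord(i, area, score, 0, "tracked"))
        else:
            if miss_count == 0:
                miss_start = i
            miss_count += 1
            state = "miss"
            if miss_count > config.patience_frames:
                history.append(TrackRecord(i, area, score, miss_count, "lost"))
                return KeyframeResult(keyframe_index=miss_start,
                                      loss_start_index=miss_start,
                                      reason=LossReason.tracking_lost,
                                      track_history=history)
            history.append(TrackRecord(i, area, score, miss_count, state))

    if reference is None:
        return KeyframeResult(keyframe_index=None, loss_start_index=None,
                              reason=LossReason.never_initialized,
                              track_history=history)
    return KeyframeResult(keyframe_index=len(frames) - 1, loss_start_index=None,
                          reason=LossReason.sequence_end_no_loss,
                          track_history=history)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_frames(path: str | Path) -> list[np.ndarray]:
    """Load a frame directory (PNG/JPEG, lexicographic order) or a video file."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise FileNotFoundError(f"no image frames in {path}")
        return [iio.imread(p) for p in files]
    return [np.asarray(f) for f in iio.imiter(path)]


def write_track_log(result: KeyframeResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "segment_area", "iou", "miss_count", "state"])
        for rec in result.track_history:
            writer.writerow([rec.frame_index, rec.segment_area,
                             f"{rec.iou:.4f}", rec.miss_count, rec.state])
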