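"""Pipeline driver and evaluation metrics.

Runs the two-step pipeline (lumen tracking to a keyframe, then single-frame
3D measurement) on a sequence, and computes the evaluation metrics used to
validate it: keyframe correctness against an annotated optimal interval,
mean absolute error of the stenosis indices against reference values, and
same-patient consistency (range and difference of repeated estimations).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .camera import CameraModel
from .lumen_tracking import (KeyframeResult, LossReason, TrackerConfig,
                             load_frames, track_sequence)
from .stenosis_metrics import StageError, StenosisReport, measure_keyframe

__all__ = [
    "SequenceSpec",
    "GroundTruth",
    "EvalReport",
    "run_pipeline",
    "run_pipeline_frames",
    "keyframe_correct",
    "mae",
    "consistency",
    "evaluate_manifest",
]

log = logging.getLogger("stenoscope")


@dataclass(frozen=True)
class SequenceSpec:
    sequence_id: str
    frames_path: str | Path
    calibration_path: str | Path
    patient_id: str | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Per-sequence annotations: the optimal keyframe interval (inclusive)
    and optional reference indices (PSA from CT, PSD from experts)."""

    keyframe_interval: tuple[int, int] | None = None
    psa_reference: float | None = None
    psd_reference: float | None = None

    def __post_init__(self) -> None:
        if self.keyframe_interval is not None:
            first, last = self.keyframe_interval
            if first > last:
                raise ValueError("keyframe interval must satisfy first <= last")


@dataclass
class EvalReport:
    correct_keyframe_pct: float | None
    per_sequence_ae_psa: dict[str, float]
    per_sequence_ae_psd: dict[str, float]
    mae_psa: float | None
    mae_psd: float | None
    consistency_psa: dict
    consistency_psd: dict


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline_frames(frames, camera: CameraModel,
                        tracker_config: TrackerConfig | None = None,
                        estimator_id: str = "photometric",
                        ) -> tuple[KeyframeResult, StenosisReport]:
    """Track a loaded frame stack to its keyframe and measure the stenosis."""
    tracker_config = tracker_config or TrackerConfig()
    t0 = time.perf_counter()
    keyframe = track_sequence(frames, tracker_config)
    log.info("tracking: %s at frame %s (%.2fs)", keyframe.reason.value,
             keyframe.keyframe_index, time.perf_counter() - t0)
    if keyframe.reason is LossReason.never_initialized:
        raise StageError("tracking", "no frame ever yielded a dark segment")
    t0 = time.perf_counter()
    report = measure_keyframe(frames[keyframe.keyframe_index], camera,
                              tracker_config=tracker_config,
                              estimator_id=estimator_id,
                              keyframe_index=keyframe.keyframe_index)
    log.info("measurement: PSA=%.2f PSD=%.2f (%.2fs)", report.psa, report.psd,
             time.perf_counter() - t0)
    return keyframe, report


def run_pipeline(spec: SequenceSpec,
                 tracker_config: TrackerConfig | None = None,
                 estimator_id: str = "photometric",
                 ) -> tuple[KeyframeResult, StenosisReport]:
    """Load a sequence from disk and run the full pipeline."""
    try:
        frames = load_frames(spec.frames_path)
        camera = CameraModel.from_file(spec.calibration_path)
        return run_pipeline_frames(frames, camera, tracker_config, estimator_id)
    except Exception as exc:
        raise RuntimeError(f"sequence {spec.sequence_id!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def keyframe_correct(selected_index: int,
                     keyframe_interval: tuple[int, int]) -> bool:
    """Whether the selected keyframe falls within the annotated optimal
    interval (inclusive bounds)."""
    first, last = keyframe_interval
    if first > last:
        raise ValueError("invalid interval")
    return first <= selected_index <= last


def mae(ground_truths, estimates) -> float:
    """Mean absolute error over paired reference values and estimates."""
    gt = np.asarray(ground_truths, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if gt.shape != est.shape:
        raise ValueError("ground truths and estimates must pair up")
    if gt.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(gt - est)))


def consistency(estimates_by_patient: dict[str, list[float]]) -> dict:
    """Per-patient estimation range and difference, plus the overall mean
    difference across patients.

    Patients with fewer than two estimates are excluded (with a warning):
    a range needs at least two repeated estimations.
    """
    per_patient: dict[str, dict] = {}
    diffs = []
    for patient, values in estimates_by_patient.items():
        vals = [float(v) for v in values]
        if len(vals) < 2:
            warnings.warn(f"patient {patient!r} has a single estimate; "
                          "excluded from consistency", stacklevel=2)
            continue
        lo, hi = min(vals), max(vals)
        diff = hi - lo
        per_patient[patient] = {"min": lo, "max": hi, "diff": diff}
        diffs.append(diff)
    if not per_patient:
        raise ValueError("no patient has two or more estimates")
    return {"per_patient": per_patient,
            "mean_diff": float(np.mean(diffs))}


# ---------------------------------------------------------------------------
# manifest-driven evaluation
# ---------------------------------------------------------------------------

def _load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def evaluate_manifest(manifest_path: str | Path, gt_path: str | Path,
                      tracker_config: TrackerConfig | None = None,
                      estimator_id: str = "photometric") -> tuple[EvalReport, pd.DataFrame]:
    """Evaluate every sequence of a manifest against a ground-truth file.

    Manifest schema: ``sequences: [{sequence_id, frames_path,
    calibration_path, patient_id}]``.  Ground truth schema, per sequence id:
    ``{keyframe_interval: [first, last], psa_reference, psd_reference}``;
    missing references are skipped per metric.
    """
    manifest = _load_yaml(manifest_path)
    gt_all = _load_yaml(gt_path)

    rows = []
    kf_flags = []
    ae_psa: dict[str, float] = {}
    ae_psd: dict[str, float] = {}
    psa_by_patient: dict[str, list[float]] = {}
    psd_by_patient: dict[str, list[float]] = {}

    for entry in manifest["sequences"]:
        spec = SequenceSpec(**entry)
        keyframe, report = run_pipeline(spec, tracker_config, estimator_id)
        gt_entry = gt_all.get(spec.sequence_id, {}) or {}
        interval = gt_entry.get("keyframe_interval")
        correct = (keyframe_correct(keyframe.keyframe_index, tuple(interval))
                   if interval is not None else None)
        if correct is not None:
            kf_flags.append(correct)
        if gt_entry.get("psa_reference") is not None:
            ae_psa[spec.sequence_id] = abs(gt_entry["psa_reference"] - report.psa)
        if gt_entry.get("psd_reference") is not None:
            ae_psd[spec.sequence_id] = abs(gt_entry["psd_reference"] - report.psd)
        if spec.patient_id:
            psa_by_patient.setdefault(spec.patient_id, []).append(report.psa)
            psd_by_patient.setdefault(spec.patient_id, []).append(report.psd)
        rows.append({
            "sequence_id": spec.sequence_id,
            "patient_id": spec.patient_id,
            "keyframe_index": keyframe.keyframe_index,
            "keyframe_reason": keyframe.reason.value,
            "keyframe_correct": correct,
            "psa": round(report.psa, 2),
            "psd": round(report.psd, 2),
            "flags": ";".join(sorted(report.flags)),
        })

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cons_psa = _safe_consistency(psa_by_patient)
        cons_psd = _safe_consistency(psd_by_patient)
    report = EvalReport(
        correct_keyframe_pct=(100.0 * np.mean(kf_flags) if kf_flags else None),
        per_sequence_ae_psa=ae_psa,
        per_sequence_ae_psd=ae_psd,
        mae_psa=(mae(list(ae_psa.values()), [0.0] * len(ae_psa))
                 if ae_psa else None),
        mae_psd=(mae(list(ae_psd.values()), [0.0] * len(ae_psd))
                 if ae_psd else None),
        consistency_psa=cons_psa,
        consistency_psd=cons_psd,
    )
    return report, pd.DataFrame(rows)


def _safe_consistency(by_patient: dict[str, list[float]]) -> dict:
    multi = {p: v for p, v in by_patient.items() if len(v) >= 2}
    if not multi:
        return {}
    return consistency(multi)
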