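"""Phantom validation studies.

These are the standard experiments used to validate the pipeline on
synthetic stenotic airways: index recovery (PSA/PSD against the phantom's
analytic truth), keyframe recovery against the known transition frame,
the photometric round trip, and scale invariance of the indices.  Each
study is deterministic given its seed.

Problem sizes: the measurement studies render 320x256 frames; the
keyframe-recovery study uses a 160x128 stream, which is ample for the
intensity-threshold tracker.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .camera import CameraModel
from .evaluation import run_pipeline_frames
from .lumen_tracking import TrackerConfig, track_sequence
from .phantom import (RenderConfig, default_phantom, make_trajectory,
                      ray_cast_depth, render_frame, render_sequence,
                      resolve_gain)
from .photometric_depth import backproject, depth_from_intensity
from .stenosis_metrics import (Plane, compute_indices, cross_section,
                               fit_plane, sweep_reference_plane)

__all__ = [
    "measurement_camera",
    "tracking_camera",
    "index_recovery_study",
    "keyframe_recovery_study",
    "round_trip_study",
    "scale_invariance_study",
]


def measurement_camera() -> CameraModel:
    return CameraModel.default(width=320, height=256)


def tracking_camera() -> CameraModel:
    return CameraModel.default(width=160, height=128)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def index_recovery_study(seed: int = 1,
                         ratios: tuple[float, ...] = (0.3, 0.5, 0.7),
                         seeds_per_ratio: int = 4,
                         camera: CameraModel | None = None) -> list[dict]:
    """Full tracking + measurement pipeline on phantoms spanning a range of
    stenosis/reference radius ratios; one record per phantom with the
    estimated and analytic PSA/PSD."""
    camera = camera or measurement_camera()
    records = []
    for ratio in ratios:
        phantom = default_phantom(stenosis_radius=10.0 * ratio)
        trajectory = make_trajectory(phantom)
        for s in _child_seeds(seed + int(1000 * ratio), seeds_per_ratio):
            frames, gt = render_sequence(
                phantom, trajectory, RenderConfig(camera=camera, seed=int(s)))
            keyframe, report = run_pipeline_frames(frames, camera)
            records.append({
                "ratio": ratio,
                "seed": int(s),
                "keyframe_index": keyframe.keyframe_index,
                "transition_index": gt.transition_index,
                "psa": report.psa,
                "psd": report.psd,
                "psa_true": 100.0 * (1.0 - ratio ** 2),
                "psd_true": 100.0 * (1.0 - ratio),
            })
    return records


def keyframe_recovery_study(seed: int = 1, n_sequences: int = 20,
                            camera: CameraModel | None = None) -> dict:
    """Track ``n_sequences`` seeded default-phantom sequences and score the
    selected keyframe against the window [T - 2, T + patience]."""
    camera = camera or tracking_camera()
    phantom = default_phantom()
    trajectory = make_trajectory(phantom)
    config = TrackerConfig()
    results = []
    for s in _child_seeds(seed, n_sequences):
        frames, gt = render_sequence(
            phantom, trajectory, RenderConfig(camera=camera, seed=int(s)))
        res = track_sequence(frames, config)
        T = gt.transition_index
        ok = (res.keyframe_index is not None
              and T - 2 <= res.keyframe_index <= T + config.patience_frames)
        results.append({"seed": int(s), "keyframe_index": res.keyframe_index,
                        "transition_index": T, "reason": res.reason.value,
                        "correct": bool(ok)})
    correct = [r["correct"] for r in results]
    return {"correct_pct": 100.0 * float(np.mean(correct)),
            "n_sequences": n_sequences, "results": results}


def round_trip_study(seed: int = 1,
                     camera: CameraModel | None = None) -> dict:
    """Render a noise-free 8-bit keyframe of the default phantom and invert
    it photometrically; returns the Pearson correlation between recovered
    and true depth over valid pixels."""
    camera = camera or measurement_camera()
    phantom = default_phantom()
    trajectory = make_trajectory(phantom)
    kf_z = float(trajectory.poses[trajectory.transition_index])
    cfg = RenderConfig(camera=camera, seed=seed, noise_sigma=0.0)
    d0, n0, _ = ray_cast_depth(phantom, float(trajectory.poses[0]), camera)
    gain = resolve_gain(d0, n0, 1.0, cfg)
    depth, normals, lumen = ray_cast_depth(phantom, kf_z, camera)
    img = render_frame(depth, normals, 1.0, replace(cfg, gain=gain))
    d_hat = depth_from_intensity(img, camera)
    ok = d_hat.valid_mask & np.isfinite(depth)
    r = float(np.corrcoef(d_hat.values[ok], depth[ok])[0, 1])
    return {"pearson_r": r, "n_pixels": int(ok.sum())}


def scale_invariance_study(seed: int = 1,
                           scales: tuple[float, ...] = (0.1, 1.0, 10.0)) -> dict:
    """PSA/PSD computed from the same synthetic cloud at several global
    scales; returns the maximum deviation across scales."""
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, 200)
    stenosis_ring = np.column_stack([np.cos(ang), np.sin(ang),
                                     np.full(200, 8.0)])
    stenosis_ring += rng.normal(0, 0.02, stenosis_ring.shape)
    zs = np.linspace(1.0, 7.5, 60)
    tube = np.vstack([np.column_stack([2 * np.cos(ang), 2 * np.sin(ang),
                                       np.full(200, z)]) for z in zs])
    cloud = np.vstack([stenosis_ring, tube])

    def indices(scale: float) -> tuple[float, float]:
        pts = cloud * scale
        plane = fit_plane(pts[:200])
        cs_s = cross_section(pts[:200], plane, 0.1 * scale)
        _, cs_r = sweep_reference_plane(pts, 1.5 * scale, 7.0 * scale,
                                        n_planes=12,
                                        slab_tolerance=0.1 * scale)
        rep = compute_indices(cs_s.area, cs_r.area, cs_s.circle_diameter,
                              cs_r.circle_diameter)
        return rep.psa, rep.psd

    base_psa, base_psd = indices(1.0)
    max_delta = 0.0
    for s in scales:
        psa, psd = indices(s)
        max_delta = max(max_delta, abs(psa - base_psa), abs(psd - base_psd))
    return {"max_delta": float(max_delta), "psa": base_psa, "psd": base_psd}
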