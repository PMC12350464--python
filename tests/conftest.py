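"""Shared fixtures: cameras and pre-rendered phantom imagery.

Rendering is the expensive part of the suite, so the default tracking
sequence and the measurement keyframe are rendered once per session.
"""

from dataclasses import replace

import numpy as np
import pytest

from stenoscope import (CameraModel, RenderConfig, default_phantom,
                        make_trajectory, ray_cast_depth, render_frame,
                        render_sequence, resolve_gain)


@pytest.fixture(scope="session")
def cam_track() -> CameraModel:
    """Tracking-grade camera (downsampled video stream)."""
    return CameraModel.default(width=160, height=128)


@pytest.fixture(scope="session")
def cam_meas() -> CameraModel:
    """Measurement-grade camera."""
    return CameraModel.default(width=320, height=256)


@pytest.fixture(scope="session")
def phantom_default():
    return default_phantom()


@pytest.fixture(scope="session")
def tracked_sequence(phantom_default, cam_track):
    """A full default-phantom sequence (frames, ground truth, trajectory)."""
    traj = make_trajectory(phantom_default)
    frames, gt = render_sequence(phantom_default, traj,
                                 RenderConfig(camera=cam_track, seed=0))
    return frames, gt, traj


@pytest.fixture(scope="session")
def keyframe_render(phantom_default, cam_meas):
    """A measurement keyframe image plus its ground-truth geometry.

    Returns (image, depth, normals, lumen_mask, gain, keyframe_z).
    """
    ph = phantom_default
    traj = make_trajectory(ph)
    kf_z = float(traj.poses[traj.transition_index])
    cfg = RenderConfig(camera=cam_meas, seed=3)
    d0, n0, _ = ray_cast_depth(ph, float(traj.poses[0]), cam_meas)
    gain = resolve_gain(d0, n0, ph.albedo, cfg)
    depth, normals, lumen = ray_cast_depth(ph, kf_z, cam_meas)
    img = render_frame(depth, normals, ph.albedo, replace(cfg, gain=gain))
    return img, depth, normals, lumen, gain, kf_z
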