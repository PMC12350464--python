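"""Pinhole camera model shared by the phantom renderer and the 3D reconstruction.

The camera is a plain pinhole with focal lengths ``fx, fy`` and principal
point ``cx, cy`` (all in pixels, 0-based pixel-centre convention: integer
pixel coordinates address pixel centres).  The sensor's gamma correction
``gamma`` is carried here because the photometric depth inversion needs it
alongside the intrinsics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["CameraModel"]


@dataclass(frozen=True)
class CameraModel:
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    gamma: float = 2.2

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            fx=float(d["fx"]), fy=float(d["fy"]),
            cx=float(d["cx"]), cy=float(d["cy"]),
            width=int(d["width"]), height=int(d["height"]),
            gamma=float(d.get("gamma", 2.2)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "CameraModel":
        """Read intrinsics from a YAML or JSON calibration file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = {k: (int(v) if isinstance(v, int) else float(v))
             for k, v in asdict(self).items()}
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d))

    @classmethod
    def default(cls, width: int = 160, height: int = 128,
                fov_deg: float = 110.0, gamma: float = 2.2) -> "CameraModel":
        """A forward endoscope-like camera with a wide field of view."""
        f = float((width / 2.0) / np.tan(np.deg2rad(fov_deg) / 2.0))
        return cls(fx=f, fy=f, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                   width=width, height=height, gamma=gamma)

    # -- geometry -----------------------------------------------------

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    def pixel_rays(self, normalize: bool = True) -> np.ndarray:
        """Per-pixel ray directions, shape (H, W, 3), camera frame.

        Camera frame is x right, y down, z forward.  With ``normalize`` the
        rays are unit vectors, so a point at Euclidean ray distance d along
        pixel (u, v) is ``d * pixel_rays()[v, u]``.
        """
        u = np.arange(self.width, dtype=float)
        v = np.arange(self.height, dtype=float)
        uu, vv = np.meshgrid(u, v)
        rays = np.stack(
            [(uu - self.cx) / self.fx, (vv - self.cy) / self.fy,
             np.ones_like(uu)], axis=-1)
        if normalize:
            rays /= np.linalg.norm(rays, axis=-1, keepdims=True)
        return rays

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project camera-frame points (N, 3) to pixel coordinates (N, 2)."""
        pts = np.asarray(points, dtype=float)
        z = pts[..., 2]
        u = self.fx * pts[..., 0] / z + self.cx
        v = self.fy * pts[..., 1] / z + self.cy
        return np.stack([u, v], axis=-1)
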