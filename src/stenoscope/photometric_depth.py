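"""Single-frame depth from illumination decline, normals and backprojection.

With the light source at the optical centre, image intensity declines with
the inverse square of the Euclidean ray distance d, gamma-encoded by the
sensor: I ~ (1/d^2)^(1/gamma).  Inverting this per pixel yields an
up-to-scale depth map d_hat = I_norm^(-gamma/2).  Depth here is Euclidean
distance along the pixel ray (not z-depth): the inverse-square law governs
physical distance from the source, so backprojection places each point at
d_hat times the *unit* pixel ray.

The analytic inversion deliberately sets albedo to 1 and ignores Lambertian
foreshortening; a learned estimator (e.g. a LightDepth-style network) can be
registered behind the same plug-in contract via :func:`register_estimator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage

from .camera import CameraModel

__all__ = [
    "DepthMap",
    "AlbedoMap",
    "NormalMap",
    "PointCloud",
    "depth_from_intensity",
    "backproject",
    "normals_from_depth",
    "estimate_depth",
    "register_estimator",
    "registered_estimators",
    "export_ply",
    "export_depth_png",
]

FLOOR_EPSILON = 0.02        # ~5/255: below this the signal is noise-floor
SATURATION_LEVEL = 250      # 8-bit level at/above which pixels count as specular


@dataclass
class DepthMap:
    """Up-to-scale per-pixel depth with a validity mask.

    ``values`` are positive everywhere (clamped at the noise-floor depth on
    invalid pixels); ``valid_mask`` is False on noise-floor and saturated
    (specular) pixels.
    """

    values: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AlbedoMap:
    values: np.ndarray  # reflectance in (0, 1]


@dataclass
class NormalMap:
    values: np.ndarray      # (H, W, 3) unit vectors, camera frame
    valid_mask: np.ndarray


@dataclass
class PointCloud:
    """Backprojected camera-frame points (x right, y down, z forward), one
    per valid pixel, at the same arbitrary scale as the source depth."""

    points: np.ndarray        # (N, 3)
    pixel_index: np.ndarray   # (N, 2) provenance (row, col) of each point

    def __len__(self) -> int:
        return len(self.points)


def depth_from_intensity(gray: np.ndarray, camera: CameraModel,
                         floor_epsilon: float = FLOOR_EPSILON,
                         saturation_level: int = SATURATION_LEVEL,
                         median_radius: int = 0) -> DepthMap:
    """Invert the illumination-decline law: d_hat = I_norm^(-gamma/2).

    Pixels at or below the noise floor carry no reliable photometric signal
    and are clamped at the floor depth with ``valid_mask`` False; saturated
    pixels (specular highlights) are likewise masked.  ``median_radius`` > 0
    applies an optional median filter to the inverted depth.
    """
    if camera.gamma <= 0:
        raise ValueError("gamma must be positive")
    if not (0 < floor_epsilon < 1):
        raise ValueError("floor_epsilon must be in (0, 1)")
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    i_norm = gray.astype(float) / 255.0
    valid = (i_norm > floor_epsilon) & (gray < saturation_level)
    d = np.maximum(i_norm, floor_epsilon) ** (-camera.gamma / 2.0)
    if median_radius > 0:
        d = ndimage.median_filter(d, size=2 * median_radius + 1)
    return DepthMap(values=d, valid_mask=valid)


def backproject(depth: DepthMap, camera: CameraModel) -> PointCloud:
    """Backproject valid pixels through the intrinsics: X = d_hat * ray."""
    if depth.values.shape != (camera.height, camera.width):
        raise ValueError("depth and camera dimensions disagree")
    rays = camera.pixel_rays()
    pts = depth.values[..., None] * rays
    rows, cols = np.nonzero(depth.valid_mask)
    return PointCloud(points=pts[rows, cols],
                      pixel_index=np.stack([rows, cols], axis=1))


def normals_from_depth(depth: DepthMap, camera: CameraModel) -> NormalMap:
    """Surface normals from finite differences of the backprojected grid.

    The normal is the normalized cross product of the column- and
    row-tangent vectors, oriented to face the camera (n . (-X) > 0).
    Pixels whose finite-difference neighbourhood includes invalid depth get
    an invalid normal.
    """
    rays = camera.pixel_rays()
    P = depth.values[..., None] * rays      # (H, W, 3) grid of points
    du = np.gradient(P, axis=1)             # along columns (x direction)
    dv = np.gradient(P, axis=0)             # along rows (y direction)
    n = np.cross(du, dv)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 1e-12)
    flip = np.einsum("hwc,hwc->hw", n, P) > 0   # ensure n . (-X) > 0
    n[flip] *= -1.0
    valid = ndimage.binary_erosion(depth.valid_mask, structure=np.ones((3, 3)))
    valid &= norm[..., 0] > 1e-12
    return NormalMap(values=n, valid_mask=valid)


# ---------------------------------------------------------------------------
# estimator plug-in contract
# ---------------------------------------------------------------------------

Estimator = Callable[[np.ndarray, CameraModel], tuple[DepthMap, AlbedoMap, NormalMap]]

_ESTIMATORS: dict[str, Estimator] = {}


def register_estimator(estimator_id: str, fn: Estimator) -> None:
    """Register a depth estimator (e.g. a learned model wrapper) under an id.

    The contract: ``fn(gray_image, camera) -> (DepthMap, AlbedoMap,
    NormalMap)`` with up-to-scale depth and a validity mask.
    """
    _ESTIMATORS[estimator_id] = fn


def registered_estimators() -> list[str]:
    return sorted(_ESTIMATORS)


def _photometric_estimator(gray: np.ndarray, camera: CameraModel,
                           ) -> tuple[DepthMap, AlbedoMap, NormalMap]:
    depth = depth_from_intensity(gray, camera)
    albedo = AlbedoMap(values=np.ones_like(depth.values))
    normals = normals_from_depth(depth, camera)
    return depth, albedo, normals


register_estimator("photometric", _photometric_estimator)


def estimate_depth(image: np.ndarray, camera: CameraModel,
                   estimator_id: str = "photometric",
                   ) -> tuple[DepthMap, AlbedoMap, NormalMap]:
    """Dispatch to a registered single-frame depth estimator."""
    from .lumen_tracking import to_grayscale

    if estimator_id not in _ESTIMATORS:
        raise KeyError(
            f"unknown estimator {estimator_id!r}; registered: "
            f"{registered_estimators()}")
    gray = to_grayscale(np.asarray(image))
    return _ESTIMATORS[estimator_id](gray, camera)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_ply(cloud: PointCloud, path: str | Path) -> None:
    """Write the point cloud as PLY (ASCII for .ply via trimesh)."""
    import trimesh

    trimesh.PointCloud(cloud.points).export(str(path))


def export_depth_png(depth: DepthMap, path: str | Path,
                     scale: float | None = None) -> float:
    """Write depth as 16-bit PNG; returns the scale used (value = depth*scale)."""
    import imageio.v3 as iio

    if scale is None:
        scale = 65535.0 / float(depth.values.max())
    img = np.clip(depth.values * scale, 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), img)
    return scale
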