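"""Synthetic stenotic-airway phantom: geometry, ray casting and rendering.

The phantom emulates the imaging situation of a bronchoscopic exploration of
subglottic stenosis: a tubular airway with a narrow vocal-cord aperture
followed by a stenotic narrowing, imaged by a forward-moving camera whose
illumination source is co-located with the optical centre.  Image intensity
follows the illumination-decline law

    I = clip(L, 0, 1)^(1/gamma),   L = gain * albedo * shade / d^2

where ``d`` is the Euclidean distance from the camera/light centre to the
surface along the pixel ray.  The default shading model is the pure
inverse-square decline (``shade = 1``); a Lambertian factor ``max(n.l, 0)``
is available as an option for robustness experiments.  Sensor noise,
specular highlights and quantization complete the model.

Geometry is a surface of revolution around a straight axis (the camera
travels on-axis), queryable through ``radius_profile(z)``, the open-lumen
radius at axial position z.  The vocal cords are modelled either as a smooth
concentric narrowing of the wall or — the default — as a thin diaphragm with
an off-centre circular aperture.  The off-centre aperture occludes the image
centre until the camera passes the cord plane, which reproduces the abrupt
change of the darkest image region observed clinically at that moment and
gives the tracking stage a well-defined transition event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np

from .camera import CameraModel

__all__ = [
    "AirwayPhantom",
    "RenderConfig",
    "Trajectory",
    "SequenceGroundTruth",
    "make_stenotic_airway",
    "make_trajectory",
    "ray_cast_depth",
    "render_frame",
    "resolve_gain",
    "render_sequence",
    "write_sequence",
]

# Intensity rendered (on the [0, 1] scale, after gamma) for rays that leave
# through the far end of the airway, where no surface returns light: the
# sensor noise floor.
NOISE_FLOOR = 5.0 / 255.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _gauss(z: np.ndarray | float, z0: float, sigma: float) -> np.ndarray | float:
    return np.exp(-0.5 * ((np.asarray(z, dtype=float) - z0) / sigma) ** 2)


@dataclass(frozen=True)
class AirwayPhantom:
    """Tubular airway with a vocal-cord aperture and a stenotic narrowing.

    All lengths in millimetres.  ``radius_profile(z)`` returns the open
    lumen radius at axial position z (the aperture radius at the two
    narrowings, the wall radius elsewhere).  ``albedo`` is the uniform
    surface reflectance in (0, 1].
    """

    axis_length: float
    base_radius: float
    stenosis_radius: float
    stenosis_z: float
    vocal_cord_radius: float
    vocal_cord_z: float
    sigma_stenosis: float = 1.5
    sigma_vocal: float = 1.5
    albedo: float = 0.8
    #: lateral (y) offset of the vocal-cord aperture centre.  Non-zero models
    #: the cords as a thin off-centre diaphragm at ``vocal_cord_z``; zero
    #: models them as a smooth concentric narrowing of the wall.
    vocal_cord_offset: float = 0.0
    #: radius of the airway proximal of the cords (the laryngeal vestibule
    #: is narrower than the trachea); None means equal to ``base_radius``.
    proximal_radius: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.stenosis_radius < self.base_radius):
            raise ValueError("need 0 < stenosis_radius < base_radius")
        if not (0 < self.vocal_cord_radius < self.base_radius):
            raise ValueError("need 0 < vocal_cord_radius < base_radius")
        if not (0 < self.vocal_cord_z < self.stenosis_z < self.axis_length):
            raise ValueError("need 0 < vocal_cord_z < stenosis_z < axis_length")
        if not (0 < self.albedo <= 1):
            raise ValueError("albedo must lie in (0, 1]")
        if self.proximal_radius is not None and self.proximal_radius <= 0:
            raise ValueError("proximal_radius must be positive")
        if (abs(self.vocal_cord_offset) + self.vocal_cord_radius
                > float(self.wall_radius(self.vocal_cord_z))):
            raise ValueError("vocal-cord aperture must lie inside the tube")

    # The wall proper: stenosis narrowing always belongs to the wall; the
    # vocal narrowing only when the cords are modelled concentrically.  A
    # narrower proximal (supraglottic) segment blends into the distal tube
    # over the cord region with a tanh ramp.
    def wall_radius(self, z: np.ndarray | float) -> np.ndarray | float:
        zz = np.asarray(z, dtype=float)
        r_prox = self.base_radius if self.proximal_radius is None else self.proximal_radius
        w = 2.0 * self.sigma_vocal
        r = r_prox + (self.base_radius - r_prox) * 0.5 * (
            1.0 + np.tanh((zz - self.vocal_cord_z) / w))
        r = r - (self.base_radius - self.stenosis_radius) * _gauss(
            zz, self.stenosis_z, self.sigma_stenosis)
        if self.vocal_cord_offset == 0.0:
            r = r - (self.base_radius - self.vocal_cord_radius) * _gauss(
                zz, self.vocal_cord_z, self.sigma_vocal)
        return r

    def wall_radius_deriv(self, z: np.ndarray | float) -> np.ndarray | float:
        zz = np.asarray(z, dtype=float)
        r_prox = self.base_radius if self.proximal_radius is None else self.proximal_radius
        w = 2.0 * self.sigma_vocal
        d = (self.base_radius - r_prox) * 0.5 / (
            w * np.cosh((zz - self.vocal_cord_z) / w) ** 2)
        d = d - ((self.base_radius - self.stenosis_radius)
                 * _gauss(zz, self.stenosis_z, self.sigma_stenosis)
                 * (-(zz - self.stenosis_z) / self.sigma_stenosis ** 2))
        if self.vocal_cord_offset == 0.0:
            d = d - ((self.base_radius - self.vocal_cord_radius)
                     * _gauss(zz, self.vocal_cord_z, self.sigma_vocal)
                     * (-(zz - self.vocal_cord_z) / self.sigma_vocal ** 2))
        return d

    def radius_profile(self, z: np.ndarray | float) -> np.ndarray | float:
        """Open-lumen radius at axial position z."""
        r = self.wall_radius(z)
        if self.vocal_cord_offset != 0.0:
            # the diaphragm aperture narrows the open lumen around the cords
            dip = (self.base_radius - self.vocal_cord_radius) * _gauss(
                z, self.vocal_cord_z, self.sigma_vocal)
            r = np.minimum(r, self.base_radius - dip) if np.ndim(r) else min(
                float(r), self.base_radius - float(dip))
        return r


def make_stenotic_airway(base_radius: float,
                         stenosis_radius: float,
                         stenosis_z: float,
                         vocal_cord_radius: float,
                         vocal_cord_z: float,
                         axis_length: float,
                         sigma_stenosis: float = 1.5,
                         sigma_vocal: float = 1.5,
                         albedo: float = 0.8,
                         vocal_cord_offset: float = 0.0,
                         proximal_radius: float | None = None) -> AirwayPhantom:
    """Build an :class:`AirwayPhantom` with Gaussian narrowings.

    The radius profile equals ``base_radius`` away from the two apertures
    and dips smoothly (Gaussian bumps of widths ``sigma_*``) to the aperture
    radii at ``vocal_cord_z`` and ``stenosis_z``.
    """
    return AirwayPhantom(
        axis_length=axis_length, base_radius=base_radius,
        stenosis_radius=stenosis_radius, stenosis_z=stenosis_z,
        vocal_cord_radius=vocal_cord_radius, vocal_cord_z=vocal_cord_z,
        sigma_stenosis=sigma_stenosis, sigma_vocal=sigma_vocal,
        albedo=albedo, vocal_cord_offset=vocal_cord_offset,
        proximal_radius=proximal_radius)


def default_phantom(stenosis_radius: float = 5.0) -> AirwayPhantom:
    """The reference phantom used throughout the test harness.

    Dimensions are adult-airway-like: a 10 mm tube, a 3.75 mm vocal-cord
    aperture offset 4.4 mm from the axis at z = 30 mm, and the stenosis at
    z = 60 mm.
    """
    return make_stenotic_airway(
        base_radius=10.0, stenosis_radius=stenosis_radius, stenosis_z=60.0,
        vocal_cord_radius=3.75, vocal_cord_z=30.0, axis_length=150.0,
        vocal_cord_offset=4.4, proximal_radius=8.0)


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """On-axis forward camera positions (mm) and the ground-truth frame at
    which the camera passes the vocal-cord plane."""

    poses: np.ndarray  # (T,) strictly increasing axial positions
    transition_index: int

    def __post_init__(self) -> None:
        poses = np.asarray(self.poses, dtype=float)
        object.__setattr__(self, "poses", poses)
        if poses.ndim != 1 or len(poses) == 0:
            raise ValueError("poses must be a non-empty 1-D array")
        if not np.all(np.diff(poses) > 0):
            raise ValueError("poses must be strictly increasing")
        if not (0 <= self.transition_index < len(poses)):
            raise ValueError("transition_index out of range")

    def __len__(self) -> int:
        return len(self.poses)


def make_trajectory(phantom: AirwayPhantom,
                    start_z: float = 5.0,
                    end_z: float | None = None,
                    n_frames: int = 90,
                    push_start_offset: float = 5.5,
                    push_end_offset: float = 0.5) -> Trajectory:
    """Forward motion emulating a bronchoscopic approach to the subglottis.

    The camera advances slowly from ``start_z`` to just before the cords,
    passes the glottis with one brisk push (physicians cross the cords
    quickly; the advance from ``vocal_cord_z - push_start_offset`` to
    ``vocal_cord_z + push_end_offset`` happens between two consecutive
    frames), then advances slowly again to ``end_z``, stopping short of the
    stenosis — the stenosed region is never traversed.  The transition
    index is the first pose past the cord plane, i.e. the frame right
    after the push.
    """
    if end_z is None:
        end_z = phantom.stenosis_z - 10.0
    pre_end = phantom.vocal_cord_z - push_start_offset
    post_start = phantom.vocal_cord_z + push_end_offset
    if not (0 <= start_z < pre_end and post_start < end_z < phantom.axis_length):
        raise ValueError("trajectory must start before the cords and end "
                         "between the cords and the stenosis")
    if n_frames < 4:
        raise ValueError("need at least 4 frames")
    # split the remaining frames between approach and subglottic phases in
    # proportion to the distance each covers
    len_pre = pre_end - start_z
    len_post = end_z - post_start
    n_pre = max(2, int(round((n_frames - 1) * len_pre / (len_pre + len_post))))
    n_post = max(2, n_frames - n_pre)
    pre = np.linspace(start_z, pre_end, n_pre)
    post = np.linspace(post_start, end_z, n_post)
    poses = np.concatenate([pre, post])
    transition = int(n_pre)
    return Trajectory(poses=poses, transition_index=transition)


# ---------------------------------------------------------------------------
# render configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    camera: CameraModel
    #: light-source intensity factor; None resolves it at the first pose so
    #: the median wall pixel renders near 0.5
    gain: float | None = None
    gamma: float | None = None  # None: use camera.gamma
    noise_sigma: float = 0.01
    specular_strength: float = 0.0
    specular_shininess: float = 40.0
    quantization: int = 8
    seed: int = 0
    #: "inverse_square" renders the pure illumination-decline law; "lambertian"
    #: adds the max(n.l, 0) foreshortening factor
    shading: str = "inverse_square"
    noise_floor: float = NOISE_FLOOR

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.quantization not in (8, 16):
            raise ValueError("quantization must be 8 or 16 bits")
        if self.shading not in ("inverse_square", "lambertian"):
            raise ValueError("shading must be 'inverse_square' or 'lambertian'")

    @property
    def effective_gamma(self) -> float:
        return self.camera.gamma if self.gamma is None else self.gamma


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def ray_cast_depth(phantom: AirwayPhantom, pose_z: float, camera: CameraModel,
                   z_step: float | None = None, n_bisect: int = 35,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cast all pixel rays from an on-axis camera at axial position ``pose_z``.

    Returns ``(depth, normals, lumen_mask)``: per-pixel Euclidean hit
    distance (mm; ``inf`` where the ray exits the far end), unit surface
    normals oriented towards the camera, and the boolean mask of far-exit
    (lumen) rays.

    The march runs on a z grid shared by all rays (the wall radius is then
    evaluated once per grid plane), with a step fine enough to resolve the
    narrowings, followed by per-ray bisection.
    """
    if not (0.0 <= pose_z < phantom.axis_length):
        raise ValueError("camera must be inside the tube")
    if phantom.radius_profile(pose_z) <= 0:
        raise ValueError("camera must be inside the tube lumen")
    if phantom.vocal_cord_offset != 0.0 and abs(pose_z - phantom.vocal_cord_z) < 1e-9:
        raise ValueError("camera exactly in the diaphragm plane")
    if z_step is None:
        z_step = min(phantom.sigma_stenosis, phantom.sigma_vocal) / 3.0

    rays = camera.pixel_rays()  # (H, W, 3) unit
    H, W = rays.shape[:2]
    dirs = rays.reshape(-1, 3)
    dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    rho_dir = np.hypot(dx, dy)

    # shared z grid from the camera to the far end; on it the ray is outside
    # the wall iff (z - z0) * rho_dir / dz >= r(z)
    n_z = max(2, int(np.ceil((phantom.axis_length - pose_z) / z_step)) + 1)
    zg = np.linspace(pose_z, phantom.axis_length, n_z)
    r_g = np.asarray(phantom.wall_radius(zg))
    lhs = np.multiply.outer((rho_dir / dz).astype(np.float32),
                            (zg - pose_z).astype(np.float32))  # (N, Z)
    outside = lhs >= r_g.astype(np.float32)[None, :]
    hit_any = outside.any(axis=1)
    first = np.argmax(outside, axis=1)

    # bracket in z between the last inside and first outside grid plane
    idx = np.arange(len(dirs))
    sel = hit_any
    z_hi = zg[first[sel]]
    z_lo = zg[np.maximum(first[sel] - 1, 0)]
    slope = (rho_dir / dz)[sel]
    for _ in range(n_bisect):
        z_m = 0.5 * (z_lo + z_hi)
        out = (z_m - pose_z) * slope >= phantom.wall_radius(z_m)
        z_hi = np.where(out, z_m, z_hi)
        z_lo = np.where(out, z_lo, z_m)
    t_hit = np.full(len(dirs), np.inf)
    t_hit[sel] = (0.5 * (z_lo + z_hi) - pose_z) / dz[sel]

    # off-centre vocal-cord diaphragm: a thin occluder at vocal_cord_z
    if phantom.vocal_cord_offset != 0.0 and pose_z < phantom.vocal_cord_z:
        t_d = (phantom.vocal_cord_z - pose_z) / dz
        x_d, y_d = t_d * dx, t_d * dy
        in_aperture = (x_d ** 2 + (y_d - phantom.vocal_cord_offset) ** 2
                       < phantom.vocal_cord_radius ** 2)
        blocked = ~in_aperture & (t_d < t_hit)
        t_hit = np.where(blocked, t_d, t_hit)
    else:
        blocked = np.zeros(len(dirs), dtype=bool)

    lumen = ~np.isfinite(t_hit)
    depth = t_hit.reshape(H, W)

    # normals: wall is a surface of revolution rho = r(z); inward normal is
    # (-x/rho, -y/rho, r'(z)) normalized.  Diaphragm hits face the camera.
    with np.errstate(invalid="ignore"):
        x_h, y_h = t_hit * dx, t_hit * dy
        z_h = pose_z + t_hit * dz
        rho_h = np.hypot(x_h, y_h)
        rho_safe = np.where(rho_h > 1e-12, rho_h, 1.0)
        rp = phantom.wall_radius_deriv(np.where(np.isfinite(z_h), z_h, 0.0))
        n = np.stack([-x_h / rho_safe, -y_h / rho_safe,
                      np.broadcast_to(rp, x_h.shape)], axis=-1)
        n[blocked] = [0.0, 0.0, -1.0]
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
        # orient towards the camera: n . (camera - X) > 0, camera - X = -t*dir
        flip = np.einsum("ij,ij->i", n, dirs) > 0
        n[flip] *= -1.0
        n[lumen] = np.nan
    normals = n.reshape(H, W, 3)
    return depth, normals, lumen.reshape(H, W)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def resolve_gain(depth: np.ndarray, normals: np.ndarray, albedo: float,
                 config: RenderConfig) -> float:
    """Gain making the median wall pixel render at intensity 0.5."""
    gamma = config.effective_gamma
    shade = _shade(depth, normals, config)
    wall = np.isfinite(depth)
    med = np.median(albedo * shade[wall] / depth[wall] ** 2)
    return float(0.5 ** gamma / med)


def _shade(depth: np.ndarray, normals: np.ndarray, config: RenderConfig) -> np.ndarray:
    if config.shading == "inverse_square":
        return np.ones_like(depth)
    rays = config.camera.pixel_rays()
    ndotl = -np.einsum("hwc,hwc->hw", normals, rays)  # l = -ray direction
    return np.clip(np.nan_to_num(ndotl), 0.0, None)


def render_frame(depth: np.ndarray, normals: np.ndarray, albedo: float,
                 config: RenderConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one frame from ground-truth geometry.

    Linear radiance ``L = gain * albedo * shade / d^2`` is gamma-encoded as
    ``I = clip(L, 0, 1)^(1/gamma)``; far-exit (non-finite depth) pixels
    render at the noise floor.  Optional specular lobe, additive Gaussian
    noise (seeded) and quantization to the configured bit depth follow.
    Returns a uint8 (or uint16) grayscale image.
    """
    gamma = config.effective_gamma
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    lumen = ~np.isfinite(depth)
    if np.any(depth[~lumen] <= 0):
        raise ValueError("depth must be positive on unmasked pixels")
    gain = config.gain
    if gain is None:
        gain = resolve_gain(depth, normals, albedo, config)

    shade = _shade(depth, normals, config)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = gain * albedo * shade / depth ** 2
    if config.specular_strength > 0:
        # Phong lobe with co-located source and viewer: view == light, the
        # reflected ray makes angle 2*acos(n.l) with it
        rays = config.camera.pixel_rays()
        ndotl = np.clip(-np.einsum("hwc,hwc->hw",
                                   np.nan_to_num(normals), rays), 0.0, 1.0)
        cos_refl = np.clip(2.0 * ndotl ** 2 - 1.0, 0.0, 1.0)
        L = L + config.specular_strength * cos_refl ** config.specular_shininess \
            / np.where(lumen, 1.0, depth) ** 2
    L = np.where(lumen, 0.0, L)
    img = np.clip(L, 0.0, 1.0) ** (1.0 / gamma)
    img = np.where(lumen, config.noise_floor, img)

    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    levels = 2 ** config.quantization - 1
    img = np.round(np.clip(img, 0.0, 1.0) * levels)
    return img.astype(np.uint8 if config.quantization == 8 else np.uint16)


@dataclass
class SequenceGroundTruth:
    """Per-sequence ground truth bundled with rendered frames."""

    depths: list[np.ndarray]
    lumen_masks: list[np.ndarray]
    transition_index: int
    stenosis_radius: float
    reference_radius: float
    poses: np.ndarray
    gain: float

    def to_json_dict(self) -> dict:
        return {
            "transition_index": self.transition_index,
            "stenosis_radius": self.stenosis_radius,
            "reference_radius": self.reference_radius,
            "poses": list(map(float, self.poses)),
            "gain": self.gain,
        }


def render_sequence(phantom: AirwayPhantom, trajectory: Trajectory,
                    config: RenderConfig,
                    ) -> tuple[np.ndarray, SequenceGroundTruth]:
    """Render one frame per pose; fully reproducible given ``config.seed``.

    The reference radius recorded in the ground truth is the widest open
    lumen between the cords and the stenosis, which is what the reference
    plane sweep of the measurement stage should recover.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(config.seed)
    frames, depths, masks = [], [], []
    gain = config.gain
    for pose_z in trajectory.poses:
        depth, normals, lumen = ray_cast_depth(phantom, float(pose_z), config.camera)
        if gain is None:
            gain = resolve_gain(depth, normals, phantom.albedo, config)
        frame = render_frame(depth, normals, phantom.albedo,
                             replace(config, gain=gain), rng=rng)
        frames.append(frame)
        depths.append(depth)
        masks.append(lumen)
    z_grid = np.linspace(phantom.vocal_cord_z, phantom.stenosis_z, 512)
    ref_radius = float(np.max(phantom.wall_radius(z_grid[z_grid > phantom.vocal_cord_z
                                                         + 2 * phantom.sigma_vocal])))
    gt = SequenceGroundTruth(
        depths=depths, lumen_masks=masks,
        transition_index=trajectory.transition_index,
        stenosis_radius=phantom.stenosis_radius,
        reference_radius=ref_radius,
        poses=trajectory.poses.copy(), gain=float(gain))
    return np.stack(frames), gt


def write_sequence(frames: np.ndarray, gt: SequenceGroundTruth,
                   out_dir: str | Path, write_depth: bool = False) -> None:
    """Write frames as zero-padded PNGs plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(out / f"{i:05d}.png", frame)
    (out / "ground_truth.json").write_text(json.dumps(gt.to_json_dict(), indent=2))
    if write_depth:
        np.savez_compressed(out / "depth_gt.npz", *gt.depths)
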