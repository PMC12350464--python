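"""Cross-section delineation and the stenosis indices PSA and PSD.

From the keyframe's up-to-scale point cloud and the dark-region (stenosis)
mask, the pipeline delineates the 3D contour of the stenotic aperture, fits
a plane to it (total least squares), intersects a thin slab around the plane
with the cloud to obtain the stenosed cross-section area, sweeps a family of
camera-perpendicular planes between the vocal cords and the stenosis to find
the largest (reference) cross-section, fits circles to both sections, and
reports

    PSA = (1 - A_stenosis / A_k) * 100
    PSD = (1 - diameter_stenosis / diameter_k) * 100

Both indices are ratios and therefore invariant to the global scale
ambiguity of single-frame photometric depth.  Values are reported unclamped;
out-of-range results are flagged, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import ndimage

from .camera import CameraModel
from .photometric_depth import DepthMap, PointCloud, backproject, estimate_depth

__all__ = [
    "Plane",
    "CrossSection",
    "StenosisReport",
    "StageError",
    "stenosis_contour_3d",
    "fit_plane",
    "cross_section",
    "sweep_reference_plane",
    "fit_circle",
    "compute_indices",
    "measure_keyframe",
]

SPARSE_SECTION_POINTS = 50
CIRCLE_RESIDUAL_FRACTION = 0.10


class StageError(RuntimeError):
    """Pipeline failure carrying the stage where it occurred."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class Plane:
    """Plane {X : normal . X = offset} with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions."""
        n = self.normal
        a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2


@dataclass
class CrossSection:
    plane: Plane
    boundary_2d: np.ndarray       # (M, 2) hull vertices, counter-clockwise
    area: float
    circle_center: np.ndarray     # (2,)
    circle_diameter: float
    circle_residual: float        # RMS residual of the circle fit
    n_points: int
    flags: set[str] = field(default_factory=set)


@dataclass
class StenosisReport:
    psa: float
    psd: float
    area_stenosis: float
    area_reference: float
    diameter_stenosis: float
    diameter_reference: float
    reference_plane_index: int = -1
    keyframe_index: int | None = None
    flags: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "psa": round(self.psa, 2),
            "psd": round(self.psd, 2),
            "area_stenosis": self.area_stenosis,
            "area_reference": self.area_reference,
            "diameter_stenosis": self.diameter_stenosis,
            "diameter_reference": self.diameter_reference,
            "reference_plane_index": self.reference_plane_index,
            "keyframe_index": self.keyframe_index,
            "flags": sorted(self.flags),
        }


# ---------------------------------------------------------------------------
# contour and plane
# ---------------------------------------------------------------------------

def stenosis_contour_3d(cloud: PointCloud, stenosis_mask: np.ndarray,
                        ) -> np.ndarray:
    """3D points whose pixels form the morphological outer edge of the mask.

    The outer edge (dilation minus mask) rims the dark aperture with pixels
    that still carry reliable photometric depth.  Mask pixels without a
    cloud point (invalid depth) are simply dropped.
    """
    mask = np.asarray(stenosis_mask, dtype=bool)
    if mask.sum() < 3:
        raise StageError("contour", "stenosis mask smaller than 3 pixels; "
                         "plane undefined")
    edge = ndimage.binary_dilation(mask, structure=np.ones((3, 3))) & ~mask
    flat_edge = np.nonzero(edge.ravel())[0]
    flat_pix = cloud.pixel_index[:, 0] * mask.shape[1] + cloud.pixel_index[:, 1]
    sel = np.isin(flat_pix, flat_edge)
    points = cloud.points[sel]
    if len(points) < 3:
        raise StageError("contour", f"only {len(points)} boundary points with "
                         "valid depth; plane undefined")
    return points


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane: smallest principal direction of the
    centred covariance; normal oriented with positive z (away from camera)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vh = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("points are collinear; plane undefined")
    normal = vh[2]
    if normal[2] < 0:
        normal = -normal
    return Plane(normal=normal, offset=float(normal @ centroid))


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------

def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area by the shoelace formula (positive when CCW)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def fit_circle(boundary_2d: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares (Kasa) circle fit.

    Solves the linear system 2*x*a + 2*y*b + c = x^2 + y^2 for the centre
    (a, b) and c = r^2 - a^2 - b^2.  Returns (center, diameter,
    rms_residual).  Exact for points lying on a circle; the circumcircle for
    three non-collinear points.
    """
    pts = np.asarray(boundary_2d, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to fit a circle")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle undefined")
    cx, cy, c = sol
    r2 = c + cx ** 2 + cy ** 2
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    r = float(np.sqrt(r2))
    residual = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
    return np.array([cx, cy]), 2.0 * r, residual


def cross_section(cloud: PointCloud | np.ndarray, plane: Plane,
                  slab_tolerance: float) -> CrossSection:
    """Intersect a slab of half-thickness ``slab_tolerance`` around the plane
    with the cloud; the section boundary is the 2D convex hull of the slab
    points projected into the plane, its area the shoelace area of the hull,
    and a circle is fitted to the hull vertices."""
    if slab_tolerance <= 0:
        raise ValueError("slab_tolerance must be positive")
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud)
    dist = plane.signed_distance(pts)
    slab = pts[np.abs(dist) <= slab_tolerance]
    if len(slab) < 3:
        raise StageError("cross_section",
                         f"only {len(slab)} points within the slab")
    e1, e2 = plane.basis()
    centred = slab - plane.offset * plane.normal
    coords = np.column_stack([centred @ e1, centred @ e2])
    try:
        hull = ConvexHull(coords)
    except QhullError as exc:
        raise StageError("cross_section", f"degenerate section: {exc}") from exc
    boundary = coords[hull.vertices]          # counter-clockwise in 2D
    area = shoelace_area(boundary)
    if area < 0:
        boundary = boundary[::-1]
        area = -area
    flags: set[str] = set()
    if len(slab) < SPARSE_SECTION_POINTS:
        flags.add("sparse_section")
    center, diameter, residual = fit_circle(boundary)
    if residual > CIRCLE_RESIDUAL_FRACTION * (diameter / 2.0):
        flags.add("circle_fit_poor")
    return CrossSection(plane=plane, boundary_2d=boundary, area=float(area),
                        circle_center=center, circle_diameter=float(diameter),
                        circle_residual=residual, n_points=len(slab),
                        flags=flags)


def sweep_reference_plane(cloud: PointCloud | np.ndarray,
                          z_min: float, z_max: float,
                          n_planes: int = 50,
                          slab_tolerance: float = 0.1,
                          ) -> tuple[int, CrossSection]:
    """Sweep camera-perpendicular planes over evenly spaced depths in
    [z_min, z_max]; the plane of maximum section area is the healthy
    reference just beyond the vocal cords.  Ties resolve to the plane
    nearest the camera (first argmax)."""
    if n_planes < 2:
        raise ValueError("need at least 2 planes")
    if not z_min < z_max:
        raise ValueError("need z_min < z_max")
    offsets = np.linspace(z_min, z_max, n_planes)
    best: tuple[int, CrossSection] | None = None
    for k, off in enumerate(offsets):
        plane = Plane(normal=np.array([0.0, 0.0, 1.0]), offset=float(off))
        try:
            section = cross_section(cloud, plane, slab_tolerance)
        except StageError:
            continue
        if best is None or section.area > best[1].area:
            best = (k, section)
    if best is None:
        raise StageError("reference_sweep", "all swept planes are degenerate")
    return best


def compute_indices(area_stenosis: float, area_reference: float,
                    diameter_stenosis: float, diameter_reference: float,
                    ) -> StenosisReport:
    """Percent stenosis by area and by diameter, unclamped.

    Negative values (reference smaller than stenosis) are flagged rather
    than clipped.
    """
    for name, val in [("area_stenosis", area_stenosis),
                      ("area_reference", area_reference),
                      ("diameter_stenosis", diameter_stenosis),
                      ("diameter_reference", diameter_reference)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    psa = (1.0 - area_stenosis / area_reference) * 100.0
    psd = (1.0 - diameter_stenosis / diameter_reference) * 100.0
    flags: set[str] = set()
    if psa < 0 or psd < 0:
        flags.add("reference_smaller_than_stenosis")
    return StenosisReport(psa=psa, psd=psd,
                          area_stenosis=area_stenosis,
                          area_reference=area_reference,
                          diameter_stenosis=diameter_stenosis,
                          diameter_reference=diameter_reference,
                          flags=flags)


# ---------------------------------------------------------------------------
# end-to-end keyframe measurement
# ---------------------------------------------------------------------------

def measure_keyframe(image: np.ndarray, camera: CameraModel,
                     tracker_config=None,
                     estimator_id: str = "photometric",
                     slab_tolerance: float | None = None,
                     n_planes: int = 50,
                     keyframe_index: int | None = None) -> StenosisReport:
    """Full single-frame measurement at the selected keyframe.

    Segments the stenosis as the darkest region (same intensity rule as the
    tracker), estimates up-to-scale depth, backprojects, delineates the
    stenosis plane and its section, sweeps reference planes between the
    camera and the stenosis, and computes PSA/PSD.

    The slab tolerance defaults to 2% of the cloud's median depth (scale
    free); the sweep spans the 5th depth percentile to the stenosis-plane
    mean depth.
    """
    from .lumen_tracking import TrackerConfig, segment_dark_region, to_grayscale

    tracker_config = tracker_config or TrackerConfig()
    gray = to_grayscale(np.asarray(image))
    seg = segment_dark_region(gray, tracker_config)
    if seg is None:
        raise StageError("segmentation", "no dark region below the intensity "
                         f"threshold {tracker_config.intensity_threshold}")

    depth, _albedo, _normals = estimate_depth(gray, camera, estimator_id)
    cloud = backproject(depth, camera)
    if len(cloud) < 3:
        raise StageError("backprojection", "too few valid depth pixels")

    contour = stenosis_contour_3d(cloud, seg.mask)
    try:
        sten_plane = fit_plane(contour)
    except ValueError as exc:
        raise StageError("plane_fit", str(exc)) from exc

    if slab_tolerance is None:
        slab_tolerance = 0.02 * float(np.median(cloud.points[:, 2]))
    # The stenosed section is delineated by the segmented dark region: slice
    # only the cloud points of that region (mask plus its outer rim), with a
    # slab wide enough to hold the contour's own scatter about the plane —
    # photometric depth noise spreads the rim along the viewing rays, and a
    # slab much thinner than that spread would miss its defining points.
    region = ndimage.binary_dilation(np.asarray(seg.mask, dtype=bool),
                                     structure=np.ones((3, 3)))
    flat_pix = cloud.pixel_index[:, 0] * region.shape[1] + cloud.pixel_index[:, 1]
    in_region = np.isin(flat_pix, np.nonzero(region.ravel())[0])
    region_cloud = PointCloud(points=cloud.points[in_region],
                              pixel_index=cloud.pixel_index[in_region])
    rim_rms = float(np.sqrt(np.mean(sten_plane.signed_distance(contour) ** 2)))
    sten_tol = max(slab_tolerance, 2.0 * rim_rms)
    sten_section = cross_section(region_cloud, sten_plane, sten_tol)

    z = cloud.points[:, 2]
    z_min = float(np.percentile(z, 5))
    z_max = float(contour[:, 2].mean())
    if z_max <= z_min:
        raise StageError("reference_sweep",
                         "stenosis plane is not beyond the near depth range")
    k, ref_section = sweep_reference_plane(cloud, z_min, z_max,
                                           n_planes=n_planes,
                                           slab_tolerance=slab_tolerance)

    report = compute_indices(sten_section.area, ref_section.area,
                             sten_section.circle_diameter,
                             ref_section.circle_diameter)
    report.reference_plane_index = k
    report.keyframe_index = keyframe_index
    report.flags |= sten_section.flags | ref_section.flags
    return report
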