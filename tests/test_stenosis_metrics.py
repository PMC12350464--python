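"""Cross-section delineation, circle fitting and the PSA/PSD indices."""

import numpy as np
import pytest

from stenoscope import (CameraModel, DepthMap, Plane, PointCloud, StageError,
                        backproject, compute_indices, cross_section, fit_circle,
                        fit_plane, measure_keyframe, stenosis_contour_3d,
                        sweep_reference_plane)
from stenoscope.stenosis_metrics import shoelace_area


def ring_cloud(radius, z, n=400, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.full(n, float(z))])
    if jitter:
        pts += rng.normal(0, jitter, size=pts.shape)
    return pts


def tube_cloud(radius_fn, z_lo, z_hi, n_z=120, n_ang=90):
    """Regular grid sampling of a surface of revolution (identical ring
    sampling at every z, so equal-radius sections tie exactly)."""
    zs = np.linspace(z_lo, z_hi, n_z)
    ang = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    pts = []
    for z in zs:
        r = radius_fn(z)
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                    np.full(n_ang, z)]))
    return np.vstack(pts)


class TestContour:
    def test_circular_mask_on_synthetic_plane_gives_ring(self):
        cam = CameraModel.default(width=64, height=48)
        rays = cam.pixel_rays()
        vals = 10.0 / rays[..., 2]                    # plane z = 10
        cloud = backproject(DepthMap(values=vals,
                                     valid_mask=np.ones_like(vals, dtype=bool)), cam)
        uu, vv = np.meshgrid(np.arange(64.0), np.arange(48.0))
        rad_px = np.hypot(uu - cam.cx, vv - cam.cy)
        mask = rad_px < 10
        ring = stenosis_contour_3d(cloud, mask)
        # ring pixels are the first outside the 10 px disc; at plane depth
        # 10 and focal length f that is radius ~ 10 * (10.5/f) .. (12/f)
        r3d = np.hypot(ring[:, 0], ring[:, 1])
        lo = 10.0 * 10.0 / cam.fx
        hi = 10.0 * 12.5 / cam.fx
        assert np.all((r3d > lo) & (r3d < hi))

    def test_contour_points_are_subset_of_cloud(self):
        cam = CameraModel.default(width=32, height=24)
        vals = np.full((24, 32), 5.0)
        cloud = backproject(DepthMap(values=vals,
                                     valid_mask=np.ones_like(vals, dtype=bool)), cam)
        mask = np.zeros((24, 32), dtype=bool)
        mask[10:14, 12:18] = True
        ring = stenosis_contour_3d(cloud, mask)
        cloud_set = {tuple(p) for p in np.round(cloud.points, 12)}
        assert all(tuple(p) in cloud_set for p in np.round(ring, 12))

    def test_tiny_mask_rejected(self):
        cam = CameraModel.default(width=16, height=12)
        vals = np.full((12, 16), 5.0)
        cloud = backproject(DepthMap(values=vals,
                                     valid_mask=np.ones_like(vals, dtype=bool)), cam)
        mask = np.zeros((12, 16), dtype=bool)
        mask[5, 5] = mask[5, 6] = True
        with pytest.raises(StageError):
            stenosis_contour_3d(cloud, mask)


class TestPlaneFit:
    def test_exact_horizontal_plane(self):
        pts = ring_cloud(3.0, 5.0)
        plane = fit_plane(pts)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.offset == pytest.approx(5.0)

    def test_tilted_plane_x_plus_z(self):
        # points on x + z = 1
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 200)
        y = rng.uniform(-1, 1, 200)
        pts = np.column_stack([x, y, 1.0 - x])
        plane = fit_plane(pts)
        np.testing.assert_allclose(plane.normal, [1 / np.sqrt(2), 0, 1 / np.sqrt(2)],
                                   atol=1e-9)
        assert np.max(np.abs(plane.signed_distance(pts))) < 1e-9

    def test_jitter_tilts_normal_less_than_2_degrees(self):
        pts = ring_cloud(3.0, 5.0, jitter=0.01, seed=42)
        plane = fit_plane(pts)
        angle = np.degrees(np.arccos(abs(plane.normal[2])))
        assert angle < 2.0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            fit_plane(pts)


class TestCrossSection:
    def test_perpendicular_cylinder_slice_recovers_circle_area(self):
        cloud = tube_cloud(lambda z: 3.0, 0.0, 10.0)
        plane = Plane(normal=np.array([0.0, 0.0, 1.0]), offset=5.0)
        cs = cross_section(cloud, plane, slab_tolerance=0.15)
        assert cs.area == pytest.approx(np.pi * 9.0, rel=0.05)
        assert cs.circle_diameter == pytest.approx(6.0, rel=0.02)

    def test_zero_slab_tolerance_rejected(self):
        with pytest.raises(ValueError):
            cross_section(ring_cloud(1.0, 0.0), Plane(np.array([0., 0., 1.]), 0.0),
                          slab_tolerance=0.0)

    def test_sparse_slab_flagged(self):
        pts = ring_cloud(2.0, 1.0, n=20)
        cs = cross_section(pts, Plane(np.array([0., 0., 1.]), 1.0), 0.1)
        assert "sparse_section" in cs.flags

    def test_area_invariant_to_inplane_rotation(self):
        pts = ring_cloud(2.5, 4.0, n=57, jitter=0.05, seed=9)
        plane = Plane(np.array([0., 0., 1.]), 4.0)
        cs1 = cross_section(pts, plane, 0.5)
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        cs2 = cross_section(pts @ R.T, plane, 0.5)
        assert cs2.area == pytest.approx(cs1.area, rel=1e-9)

    def test_boundary_is_counter_clockwise(self):
        pts = ring_cloud(2.0, 0.0, n=50)
        cs = cross_section(pts, Plane(np.array([0., 0., 1.]), 0.0), 0.1)
        assert shoelace_area(cs.boundary_2d) > 0


class TestReferenceSweep:
    def test_bulge_maximises_at_known_radius(self):
        bulge = lambda z: 5.0 + 3.0 * np.exp(-0.5 * ((z - 5.0) / 1.0) ** 2)
        cloud = tube_cloud(bulge, 0.0, 10.0, n_z=200)
        k, cs = sweep_reference_plane(cloud, 0.5, 9.5, n_planes=40,
                                      slab_tolerance=0.08)
        assert cs.area == pytest.approx(np.pi * 64.0, rel=0.05)

    def test_constant_tube_tie_breaks_to_first_plane(self):
        cloud = tube_cloud(lambda z: 3.0, 0.0, 10.0, n_z=201)
        # offsets chosen so every plane slices an identical sampled ring
        k, cs = sweep_reference_plane(cloud, 1.0, 9.0, n_planes=5,
                                      slab_tolerance=0.03)
        assert k == 0

    def test_selected_area_is_the_maximum(self):
        bulge = lambda z: 4.0 + 2.0 * np.exp(-0.5 * ((z - 7.0) / 1.5) ** 2)
        cloud = tube_cloud(bulge, 0.0, 10.0, n_z=150)
        k, best = sweep_reference_plane(cloud, 0.5, 9.5, n_planes=20,
                                        slab_tolerance=0.1)
        offsets = np.linspace(0.5, 9.5, 20)
        for off in offsets:
            try:
                cs = cross_section(cloud, Plane(np.array([0., 0., 1.]),
                                                float(off)), 0.1)
            except StageError:
                continue
            assert cs.area <= best.area + 1e-12


class TestCircleFit:
    def test_exact_points_on_unit_circle(self):
        pts = ring_cloud(1.0, 0.0, n=8)[:, :2]
        center, diameter, resid = fit_circle(pts)
        np.testing.assert_allclose(center, [0, 0], atol=1e-12)
        assert diameter == pytest.approx(2.0)
        assert resid < 1e-12

    def test_jittered_circle_radius_3(self):
        rng = np.random.default_rng(5)
        ang = rng.uniform(0, 2 * np.pi, 200)
        pts = np.column_stack([1.0 + 3.0 * np.cos(ang),
                               -2.0 + 3.0 * np.sin(ang)])
        pts += rng.normal(0, 0.01, pts.shape)
        center, diameter, _ = fit_circle(pts)
        np.testing.assert_allclose(center, [1.0, -2.0], atol=0.01)
        assert diameter == pytest.approx(6.0, abs=0.05)

    def test_three_points_give_circumcircle(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        center, diameter, resid = fit_circle(pts)
        # closed-form circumcentre of the triangle
        ax, ay = pts[0]; bx, by = pts[1]; cx_, cy_ = pts[2]
        d = 2 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
        ux = ((ax**2 + ay**2) * (by - cy_) + (bx**2 + by**2) * (cy_ - ay)
              + (cx_**2 + cy_**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx_ - bx) + (bx**2 + by**2) * (ax - cx_)
              + (cx_**2 + cy_**2) * (bx - ax)) / d
        np.testing.assert_allclose(center, [ux, uy], atol=1e-9)
        assert resid < 1e-9

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        with pytest.raises(ValueError):
            fit_circle(pts)


class TestIndices:
    def test_equal_sections_give_zero(self):
        rep = compute_indices(4.0, 4.0, 2.0, 2.0)
        assert rep.psa == 0.0 and rep.psd == 0.0 and not rep.flags

    def test_circular_section_consistency(self):
        rep = compute_indices(1.0, 4.0, 1.0, 2.0)
        assert rep.psa == pytest.approx(75.0)
        assert rep.psd == pytest.approx(50.0)

    def test_negative_index_flagged_not_clipped(self):
        rep = compute_indices(1.2, 1.0, 1.0, 1.0)
        assert rep.psa == pytest.approx(-20.0)
        assert "reference_smaller_than_stenosis" in rep.flags

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_indices(0.0, 1.0, 1.0, 1.0)


class TestScaleInvariance:
    def test_indices_invariant_under_cloud_scaling(self):
        rng = np.random.default_rng(12)
        sten = ring_cloud(1.0, 8.0, n=150, jitter=0.02, seed=1)
        tube = tube_cloud(lambda z: 2.0, 1.0, 7.5, n_z=80)
        cloud = np.vstack([sten, tube])

        def indices(pts, s):
            pts = pts * s
            plane = fit_plane(pts[:len(sten)])
            tol = 0.02 * float(np.median(pts[:, 2]))
            cs_s = cross_section(pts[:len(sten)], plane, max(tol, 0.1 * s))
            k, cs_r = sweep_reference_plane(pts, 1.5 * s, 7.0 * s,
                                            n_planes=12, slab_tolerance=0.1 * s)
            rep = compute_indices(cs_s.area, cs_r.area, cs_s.circle_diameter,
                                  cs_r.circle_diameter)
            return rep.psa, rep.psd, cs_s.area, cs_s.circle_diameter

        base = indices(cloud, 1.0)
        for s in (0.1, 10.0):
            scaled = indices(cloud, s)
            assert scaled[0] == pytest.approx(base[0], abs=1e-6)
            assert scaled[1] == pytest.approx(base[1], abs=1e-6)
            assert scaled[2] == pytest.approx(base[2] * s * s, rel=1e-9)
            assert scaled[3] == pytest.approx(base[3] * s, rel=1e-9)


class TestMeasureKeyframe:
    def test_phantom_keyframe_recovers_indices(self, keyframe_render, cam_meas):
        img, _, _, _, _, _ = keyframe_render
        rep = measure_keyframe(img, cam_meas)
        # default phantom: stenosis radius 5, reference radius 10
        assert rep.psd == pytest.approx(50.0, abs=5.0)
        assert rep.psa == pytest.approx(75.0, abs=5.0)
        assert rep.reference_plane_index >= 0

    def test_image_without_dark_region_fails_in_segmentation(self, cam_meas):
        img = np.full((cam_meas.height, cam_meas.width), 200, dtype=np.uint8)
        with pytest.raises(StageError, match="segmentation"):
            measure_keyframe(img, cam_meas)

    def test_intensity_rescaling_leaves_indices_nearly_unchanged(
            self, keyframe_render, cam_meas):
        # brightening by 5% corresponds to a global depth-scale change of
        # 1.05^(-gamma/2); PSA/PSD are ratios and must stay put
        img, *_ = keyframe_render
        rep = measure_keyframe(img, cam_meas)
        rep2 = measure_keyframe(np.clip(img.astype(float) * 1.05, 0, 255),
                                cam_meas)
        assert rep2.psa == pytest.approx(rep.psa, abs=0.5)
        assert rep2.psd == pytest.approx(rep.psd, abs=0.5)
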