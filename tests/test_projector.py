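"""Cone-beam and parallel projection: geometry, oracles, conservation."""

import numpy as np
import pytest

from shouldersim import (
    AnalyticBody,
    ProjectionGeometry,
    Ray,
    Volume3D,
    forward_project,
    make_view,
    parallel_project,
    rasterize_bodies,
    window_output,
)
from shouldersim.errors import GeometryError, ParameterError
from shouldersim.volume_io import Radiograph2D


@pytest.fixture(scope="module")
def smooth_sphere():
    body = AnalyticBody("sphere", {"center": (23.5, 23.5, 23.5), "radius": 16.0}, 1.0)
    return rasterize_bodies([body], (48, 48, 48), (1, 1, 1))


SMALL_GEOM = dict(sid=500.0, sdd=575.0, detector_shape=(64, 64), pitch=1.0)


class TestForwardProject:
    def test_zero_volume_projects_to_zero(self):
        v = Volume3D(np.zeros((16, 16, 16)), spacing=(1, 1, 1))
        r = forward_project(v, ProjectionGeometry(**SMALL_GEOM))
        assert np.all(r.pixels == 0)
        assert r.magnification == pytest.approx(575 / 500)

    def test_central_ray_through_slab_gives_thickness(self):
        # uniform slab 7 voxels thick along the beam axis
        vox = np.zeros((32, 32, 32))
        vox[:, 12:19, :] = 1.0
        v = Volume3D(vox, spacing=(1, 1, 1))
        g = ProjectionGeometry(**{**SMALL_GEOM, "step_fraction": 0.25})
        r = forward_project(v, g)
        central = r.pixels[31, 31]  # nearest pixel to the central ray
        assert central == pytest.approx(7.0, abs=2 * 0.25)

    def test_linearity(self, smooth_sphere):
        rng = np.random.default_rng(0)
        other = Volume3D(rng.random(smooth_sphere.shape), smooth_sphere.spacing)
        g = ProjectionGeometry(**SMALL_GEOM)
        combo = Volume3D(2.0 * smooth_sphere.voxels + 3.0 * other.voxels, smooth_sphere.spacing)
        lhs = forward_project(combo, g).pixels
        rhs = 2.0 * forward_project(smooth_sphere, g).pixels + 3.0 * forward_project(other, g).pixels
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_step_refinement_converges(self, smooth_sphere):
        g1 = ProjectionGeometry(**{**SMALL_GEOM, "step_fraction": 0.5})
        g2 = ProjectionGeometry(**{**SMALL_GEOM, "step_fraction": 0.25})
        r1 = forward_project(smooth_sphere, g1).pixels
        r2 = forward_project(smooth_sphere, g2).pixels
        scale = np.abs(r2).max()
        assert np.abs(r1 - r2).max() / scale < 0.005

    def test_magnification_scales_shadow(self):
        body = AnalyticBody("sphere", {"center": (23.5, 23.5, 23.5), "radius": 8.0}, 1.0)
        v = rasterize_bodies([body], (48, 48, 48), (1, 1, 1))
        g = ProjectionGeometry(sid=400.0, sdd=600.0, detector_shape=(128, 128), pitch=0.5)
        r = forward_project(v, g)
        row = r.pixels[63]
        cols = np.nonzero(row > row.max() / 2)[0]  # FWHM of the shadow profile
        width_mm = (cols[-1] - cols[0] + 1) * r.pitch
        # FWHM of a sphere chord profile ~ diameter * sqrt(3)/2, magnified
        expected = 16.0 * np.sqrt(3) / 2 * 1.5
        assert width_mm == pytest.approx(expected, rel=0.05)

    def test_source_inside_volume_rejected(self):
        v = Volume3D(np.zeros((16, 16, 16)), spacing=(1, 1, 1))
        with pytest.raises(GeometryError, match="behind"):
            forward_project(v, ProjectionGeometry(sid=5.0, sdd=600.0, detector_shape=(8, 8), pitch=4.0))


class TestParallelProject:
    def test_axis_projection_is_exact_sum(self):
        rng = np.random.default_rng(1)
        v = Volume3D(rng.random((10, 12, 14)), spacing=(0.5, 0.5, 0.5))
        r = parallel_project(v, "y")
        assert r.pixels.sum() == pytest.approx(v.voxels.sum() * 0.5, rel=1e-12)
        assert r.magnification == 1.0

    def test_mass_conservation(self):
        rng = np.random.default_rng(2)
        v = Volume3D(rng.random((8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        for ax in ("x", "y", "z"):
            r = parallel_project(v, ax)
            # total signal x pixel area == voxel mass x voxel volume
            assert (r.pixels * r.pitch**2).sum() == pytest.approx(v.voxels.sum() * 8.0, rel=1e-12)

    def test_rotated_volume_matches_other_axis(self):
        # cube phantom: rotating 90 deg about z maps the x-projection to the y-projection
        vox = np.zeros((32, 32, 32))
        vox[10:22, 8:20, 12:24] = 1.0
        v = Volume3D(vox, spacing=(1, 1, 1))
        rot = Volume3D(np.rot90(vox, k=1, axes=(0, 1)).copy(), v.spacing)
        px = parallel_project(rot, "x").pixels
        py = parallel_project(v, "y").pixels
        # rotation about z flips the projected in-plane axis
        np.testing.assert_allclose(px, py[:, ::-1], atol=1e-12)

    def test_oblique_parallel_matches_axis(self):
        body = AnalyticBody("sphere", {"center": (15.5, 15.5, 15.5), "radius": 9.0}, 1.0)
        v = rasterize_bodies([body], (32, 32, 32), (1, 1, 1))
        r0 = parallel_project(v, 0.0)
        ry = parallel_project(v, "y")
        assert r0.pixels.max() == pytest.approx(ry.pixels.max(), rel=0.01)


class TestViewsAndWindowing:
    def test_ap_is_angle_zero_and_y_aliases_custom(self):
        ap = make_view("AP")
        assert ap.view_angle == 0.0
        y = make_view("Y")
        c = make_view("custom", 45.0)
        assert y.view_angle == c.view_angle == 45.0

    def test_angle_range_enforced(self):
        with pytest.raises(ParameterError):
            make_view("custom", 200.0)
        with pytest.raises(ParameterError):
            make_view("custom")

    def test_geometry_invariants(self):
        with pytest.raises(GeometryError):
            ProjectionGeometry(sid=1200.0, sdd=1000.0)
        with pytest.raises(GeometryError):
            ProjectionGeometry(step_fraction=0.0)
        with pytest.raises(GeometryError):
            Ray((0, 0, 0), (1, 1, 0))

    def test_minmax_window_and_idempotence(self):
        rng = np.random.default_rng(3)
        r = Radiograph2D(rng.normal(0, 5, (16, 16)), pitch=1.0)
        w1 = window_output(r, "minmax")
        assert w1.pixels.min() == 0.0 and w1.pixels.max() == 1.0
        w2 = window_output(w1, "minmax")
        np.testing.assert_allclose(w2.pixels, w1.pixels, atol=1e-15)

    def test_percentile_window_clips_tails(self):
        r = Radiograph2D(np.arange(10000, dtype=float).reshape(100, 100), pitch=1.0)
        w = window_output(r, "percentile", (1, 99))
        assert np.mean(w.pixels == 0.0) == pytest.approx(0.01, abs=0.002)
        assert np.mean(w.pixels == 1.0) == pytest.approx(0.01, abs=0.002)

    def test_constant_image_windows_to_zero_with_warning(self):
        r = Radiograph2D(np.full((8, 8), 4.0), pitch=1.0)
        with pytest.warns(UserWarning, match="window"):
            w = window_output(r, "minmax")
        assert np.all(w.pixels == 0.0)


class TestApViewAnatomy:
    def test_head_and_glenoid_shadows_overlap_laterally(self, noiseless_phantom):
        from shouldersim import analytic_projection

        _, _, bodies = noiseless_phantom
        head = [b for b in bodies if b.shape == "sphere" and "inner_radius" not in b.params][0]
        glenoid = [b for b in bodies if "inner_radius" in b.params][0]
        g = make_view("AP", detector_shape=(96, 96), pitch=1.5, sid=1000.0, sdd=1150.0)
        iso = (47.5, 47.5, 31.5)
        head_img = analytic_projection([AnalyticBody(head.shape, head.params, 1.0)], g, isocenter=iso)
        glen_img = analytic_projection([AnalyticBody(glenoid.shape, glenoid.params, 1.0)], g, isocenter=iso)
        head_cols = np.nonzero(head_img.pixels.sum(axis=0) > 0)[0]
        glen_cols = np.nonzero(glen_img.pixels.sum(axis=0) > 0)[0]
        assert len(set(head_cols) & set(glen_cols)) > 0
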