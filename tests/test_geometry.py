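"""Flask wall profile: angles, radii, volumes, normals."""

import math

import numpy as np
import pytest

from shakeflask.geometry import (
    FlaskDimensions,
    FlaskGeometry,
    cone_half_angle_from_dims,
    solve_smooth_transition,
)


class TestConeHalfAngle:
    def test_printed_dimensions(self, dims):
        # 81.6 mm at 14.5 mm tapering to 30.7 mm at 99 mm
        assert cone_half_angle_from_dims(dims) == pytest.approx(16.76, abs=5e-3)

    def test_cylinder_limit_is_zero(self):
        dims = FlaskDimensions(max_diameter=81.6, top_diameter=81.6 - 1e-12,
                               bottom_diameter=81.6 - 29.0, torus_radius=14.5)
        assert cone_half_angle_from_dims(dims) == pytest.approx(0.0, abs=1e-9)

    def test_hand_arctan(self):
        dims = FlaskDimensions(max_diameter=80.0, top_diameter=40.0,
                               height_of_max_diameter=10.0, top_height=110.0,
                               torus_radius=14.5, bottom_diameter=80 - 29.0)
        # radial taper 20 mm over 100 mm height
        assert cone_half_angle_from_dims(dims) == pytest.approx(
            math.degrees(math.atan(20.0 / 100.0)), rel=1e-12)

    def test_degenerate_heights_rejected(self):
        with pytest.raises(ValueError):
            FlaskDimensions(top_height=14.5)


class TestSmoothTransition:
    def test_default_dims_reproduce_arc_angle(self, dims):
        arc, cone = solve_smooth_transition(dims)
        assert arc == pytest.approx(107.2, abs=0.1)
        # the recomputed cone slope matches the chord from the solved end
        # point, scanned densely as an independent check
        phis = np.linspace(90.01, 129.99, 40000)
        rt, Rc = dims.torus_radius, dims.center_circle_radius
        r_end = Rc + rt * np.sin(np.radians(phis))
        z_end = rt * (1 - np.cos(np.radians(phis)))
        tangent = np.cos(np.radians(phis)) / np.sin(np.radians(phis))
        chord = (dims.top_radius - r_end) / (dims.top_height - z_end)
        best = phis[np.argmin(np.abs(tangent - chord))]
        assert arc == pytest.approx(best, abs=2e-3)
        assert cone == pytest.approx(
            math.degrees(math.atan2(r_end[np.argmin(np.abs(tangent - chord))]
                                    - dims.top_radius,
                                    dims.top_height
                                    - z_end[np.argmin(np.abs(tangent - chord))])),
            abs=1e-2)

    def test_zero_slope_rim_gives_quarter_torus(self):
        # top rim (almost) directly above the torus end point: the chord
        # is (almost) vertical, so tangency occurs at (almost) 90 deg
        rt = 14.5
        dims = FlaskDimensions(torus_radius=rt, max_diameter=81.6,
                               height_of_max_diameter=rt,
                               top_diameter=81.6 - 1e-7, top_height=99.0,
                               bottom_diameter=81.6 - 2 * rt)
        arc, cone = solve_smooth_transition(dims)
        assert arc == pytest.approx(90.0, abs=1e-3)
        assert cone == pytest.approx(0.0, abs=1e-3)

    def test_smooth_profile_differentiable_at_junction(self, smooth_geom):
        zj = smooth_geom.junction_height
        eps = 1e-6
        below = smooth_geom.profile_slope(zj - eps)
        above = smooth_geom.profile_slope(zj + eps)
        assert abs(below - above) < 1e-4  # slopes collinear by construction

    def test_sharp_profile_kinks_at_junction(self, sharp_geom):
        zj = sharp_geom.junction_height
        eps = 1e-6
        below = sharp_geom.profile_slope(zj - eps)
        above = sharp_geom.profile_slope(zj + eps)
        assert abs(below - above) > 0.1


class TestWallRadius:
    @pytest.mark.parametrize("z, expected", [
        (0.0, 26.3),  # flat bottom radius
        (99.0, 15.35),  # top rim
    ])
    def test_boundary_radii(self, smooth_geom, sharp_geom, z, expected):
        for g in (smooth_geom, sharp_geom):
            assert g.radius_at(z) == pytest.approx(expected, abs=1e-9)

    def test_sharp_max_diameter_at_quarter_torus(self, sharp_geom):
        assert sharp_geom.radius_at(14.5) == pytest.approx(40.8, abs=1e-9)

    def test_variants_agree_below_quarter_torus_only(self, smooth_geom, sharp_geom):
        z_low = np.linspace(0.0, 14.5, 30)
        np.testing.assert_allclose(smooth_geom.radius_at(z_low),
                                   sharp_geom.radius_at(z_low), atol=1e-12)
        z_mid = np.linspace(15.0, smooth_geom.junction_height - 0.1, 20)
        assert np.all(np.abs(smooth_geom.radius_at(z_mid)
                             - sharp_geom.radius_at(z_mid)) > 1e-4)

    def test_out_of_range_rejected(self, smooth_geom):
        with pytest.raises(ValueError):
            smooth_geom.radius_at(-1.0)
        with pytest.raises(ValueError):
            smooth_geom.radius_at(100.0)


class TestInnerVolume:
    def test_zero_at_bottom_and_monotone(self, smooth_geom):
        assert smooth_geom.inner_volume_below_height(0.0) == 0.0
        zs = np.linspace(1.0, 99.0, 15)
        vols = [smooth_geom.inner_volume_below_height(z) for z in zs]
        assert np.all(np.diff(vols) > 0)

    @pytest.mark.parametrize("variant", ["sharp", "smooth"])
    def test_against_monte_carlo(self, dims, variant, rng):
        """Quadrature volume vs point-counting in a bounding cylinder."""
        geom = FlaskGeometry(dims, variant)
        r_max = geom.max_radius
        n = 4_000_000
        for z_top in rng.uniform(5.0, 99.0, size=5):
            pts = rng.uniform(size=(n, 3))
            x = (2 * pts[:, 0] - 1) * r_max
            y = (2 * pts[:, 1] - 1) * r_max
            z = pts[:, 2] * z_top
            inside = np.hypot(x, y) <= geom.radius_at(z)
            v_mc = inside.mean() * (2 * r_max) ** 2 * z_top
            v_quad = geom.inner_volume_below_height(float(z_top))
            assert v_quad == pytest.approx(v_mc, rel=2e-3)

    def test_quarter_torus_section_closed_form(self, sharp_geom):
        """Volume below the torus top equals the solid-of-revolution
        closed form: int_0^{zj} pi (Rc + rt sin phi)^2 dz."""
        rt, Rc = 14.5, 26.3
        # z = rt (1 - cos phi), dz = rt sin phi dphi
        phi = np.linspace(0.0, np.pi / 2, 200001)
        integrand = np.pi * (Rc + rt * np.sin(phi)) ** 2 * rt * np.sin(phi)
        v_exact = np.trapezoid(integrand, phi)
        assert sharp_geom.inner_volume_below_height(14.5) == pytest.approx(
            v_exact, rel=1e-6)

    def test_height_for_volume_roundtrip(self, smooth_geom):
        for v_mL in (5.0, 40.0, 120.0):
            z = smooth_geom.height_for_volume(v_mL * 1000.0)
            assert smooth_geom.inner_volume_below_height(z) == pytest.approx(
                v_mL * 1000.0, rel=1e-6)


class TestWallPointAndNormal:
    def test_normal_is_unit_and_inward(self, smooth_geom):
        z = np.linspace(0.5, 98.5, 40)
        az = np.linspace(0.0, 359.0, 40)
        pts, nrm = smooth_geom.wall_point_and_normal(z, az)
        np.testing.assert_allclose(np.linalg.norm(nrm, axis=-1), 1.0, atol=1e-12)
        # stepping inward must reduce / keep the distance to the axis
        probe = pts + 0.5 * nrm
        r_probe = np.hypot(probe[..., 0], probe[..., 1])
        r_wall = np.hypot(pts[..., 0], pts[..., 1])
        assert np.all(r_probe < r_wall + 1e-9)
        assert np.all(smooth_geom.contains(probe))

    def test_sharp_normal_jumps_at_junction(self, sharp_geom):
        _, below = sharp_geom.wall_point_and_normal(14.5 - 1e-6, 0.0)
        _, above = sharp_geom.wall_point_and_normal(14.5 + 1e-6, 0.0)
        assert np.linalg.norm(below - above) > 0.1

    def test_smooth_normal_continuous_at_junction(self, smooth_geom):
        zj = smooth_geom.junction_height
        _, below = smooth_geom.wall_point_and_normal(zj - 1e-6, 0.0)
        _, above = smooth_geom.wall_point_and_normal(zj + 1e-6, 0.0)
        assert np.linalg.norm(below - above) < 1e-4

    def test_cylinder_limit_normal_horizontal(self):
        # tall dims with equal-ish diameters: above the junction the wall is
        # nearly vertical so the cone normal is nearly horizontal
        dims = FlaskDimensions(max_diameter=81.6, top_diameter=81.59999,
                               bottom_diameter=81.6 - 29.0)
        g = FlaskGeometry(dims, "sharp")
        _, n = g.wall_point_and_normal(50.0, 90.0)
        assert abs(n[2]) < 1e-4
        assert np.allclose(n[:2] / np.linalg.norm(n[:2]), [0.0, -1.0], atol=1e-6)


class TestWallDistance:
    def test_probe_offsets_recovered(self, smooth_geom):
        z = np.linspace(0.0, 98.0, 50)
        az = np.linspace(0.0, 350.0, 36)
        Z, AZ = np.meshgrid(z, az, indexing="ij")
        pts, nrm = smooth_geom.wall_point_and_normal(Z, AZ)
        for off in (0.05, 0.45, 1.05):
            probe = pts + off * nrm
            r = np.hypot(probe[..., 0], probe[..., 1])
            d = smooth_geom.wall_distance(r, probe[..., 2])
            np.testing.assert_allclose(d, off, atol=1e-9)
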