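"""Slice ellipse fitting, curvature-radius fitting and the five parameters."""

import math

import numpy as np
import pytest

from canalssm import (CanalParams, FeatureError, FitError, PlanarPolygon,
                      RigidTransform, STRAIGHT, canal_features,
                      compute_features, extract_slices, fit_ellipse,
                      generate_canal, radius_of_curvature)


def _ring(a, b, theta_deg=0.0, center=(0.0, 0.0), n=32):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    th = np.radians(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return PlanarPolygon(0.0, (R @ np.vstack([x, y])).T + np.asarray(center))


class TestFitEllipse:
    def test_circle(self):
        e = fit_ellipse(_ring(5.0, 5.0, center=(2.0, -1.0)))
        assert abs(e.ax_max - 10.0) < 1e-9
        assert abs(e.ax_min - 10.0) < 1e-9
        assert abs(e.area - 25.0 * math.pi) < 1e-9
        assert np.allclose(e.centroid, [2.0, -1.0], atol=1e-9)

    def test_axis_aligned_ellipse(self):
        e = fit_ellipse(_ring(10.0, 5.0))
        assert abs(e.ax_max - 20.0) < 1e-9
        assert abs(e.ax_min - 10.0) < 1e-9
        assert min(e.orientation_deg, 180.0 - e.orientation_deg) < 1e-6

    @pytest.mark.parametrize("angle", [30.0, 75.0, 120.0])
    def test_rotation_leaves_axes_invariant(self, angle):
        e = fit_ellipse(_ring(10.0, 5.0, theta_deg=angle))
        assert abs(e.ax_max - 20.0) < 1e-9
        assert abs(e.ax_min - 10.0) < 1e-9
        assert abs(e.orientation_deg - angle) < 1e-6

    def test_degenerate_points(self):
        t = np.linspace(0.0, 1.0, 12)
        line = PlanarPolygon(0.0, np.c_[t, 2.0 * t])
        with pytest.raises(FitError):
            fit_ellipse(line)


class TestExtractSlices:
    def test_grid_arithmetic(self):
        p = CanalParams(length_mm=80.0, curvature_radius_mm=STRAIGHT,
                        diameter_distal_mm=12.0, diameter_min_mm=12.0,
                        ellipticity_mm=0.0, z_min_frac=0.5, proximal_flare_mm=0.0)
        slices = extract_slices(generate_canal(p, 32, 41), spacing=10.0)
        assert [s.station for s in slices] == [0.0, 10, 20, 30, 40, 50, 60, 70]

    def test_cylinder_slices(self, cylinder_mesh):
        for s in extract_slices(cylinder_mesh):
            assert abs(s.ax_max - 12.0) < 0.05
            assert abs(s.ax_min - 12.0) < 0.05
            assert np.linalg.norm(s.centroid) < 0.01

    def test_arc_centroids_on_generator_centerline(self, curved_mesh, curved_params):
        slices = extract_slices(curved_mesh)
        Rc, L = curved_params.curvature_radius_mm, curved_params.length_mm
        phi = math.radians(curved_params.bow_plane_deg)
        for s in slices:
            g = math.sqrt(Rc ** 2 - (s.station - L / 2) ** 2) \
                - math.sqrt(Rc ** 2 - (L / 2) ** 2)
            assert abs(s.centroid[0] - g * math.sin(phi)) < 0.05
            assert abs(s.centroid[1] - g * math.cos(phi)) < 0.05

    def test_too_short_mesh(self):
        p = CanalParams(length_mm=15.0, curvature_radius_mm=STRAIGHT,
                        diameter_distal_mm=12.0, diameter_min_mm=12.0,
                        ellipticity_mm=0.0, z_min_frac=0.5, proximal_flare_mm=0.0)
        with pytest.raises(FeatureError):
            extract_slices(generate_canal(p, 24, 10))


class TestRadiusOfCurvature:
    def test_exact_arc(self):
        t = np.linspace(-0.1, 0.1, 15)
        pts = np.c_[np.zeros_like(t), 700 * np.cos(t), 700 * np.sin(t)]
        assert abs(radius_of_curvature(pts) - 700.0) / 700.0 < 1e-6

    def test_tilted_plane_arc(self):
        t = np.linspace(-0.15, 0.15, 20)
        circ = np.c_[400 * np.cos(t), 400 * np.sin(t), np.zeros_like(t)]
        axis = np.array([1.0, 2.0, 0.5])
        T = RigidTransform.from_rotvec(0.7 * axis / np.linalg.norm(axis),
                                       [5.0, -3.0, 10.0])
        assert abs(radius_of_curvature(T.apply(circ)) - 400.0) / 400.0 < 1e-6

    def test_collinear_is_straight(self):
        t = np.linspace(0, 100, 12)
        pts = np.c_[np.zeros_like(t), np.zeros_like(t), t]
        assert math.isinf(radius_of_curvature(pts))

    def test_huge_radius_capped(self):
        t = np.linspace(-0.001, 0.001, 9)
        R = 80_000.0
        pts = np.c_[np.zeros_like(t), R * np.cos(t), R * np.sin(t)]
        assert math.isinf(radius_of_curvature(pts))

    def test_noisy_arc_matches_grid_search_oracle(self):
        """Kåsa + one Gauss-Newton step vs brute-force geometric residual."""
        rng = np.random.default_rng(0)
        t = np.linspace(-0.2, 0.2, 15)
        u = 400 * np.sin(t) + rng.normal(0, 0.1, t.size)
        v = 400 * (1 - np.cos(t)) + rng.normal(0, 0.1, t.size)
        pts = np.c_[u, v, np.zeros_like(t)]
        fitted = radius_of_curvature(pts)

        def geom_cost(uc, vc, r):
            return np.sum((np.hypot(u - uc, v - vc) - r) ** 2)

        best = (np.inf, None)
        for uc in np.linspace(-2, 2, 41):
            for vc in np.linspace(395, 405, 101):
                r = np.hypot(u - uc, v - vc).mean()
                cost = geom_cost(uc, vc, r)
                if cost < best[0]:
                    best = (cost, r)
        assert abs(fitted - best[1]) / best[1] < 0.01

    def test_too_few_points(self):
        with pytest.raises(FeatureError):
            radius_of_curvature(np.zeros((2, 3)))


class TestComputeFeatures:
    def test_straight_cylinder(self, cylinder_mesh):
        f = canal_features(cylinder_mesh)
        assert f.length_mm == pytest.approx(150.0, abs=1e-9)
        assert f.ellipticity_mm < 0.05
        assert abs(f.mean_diameter_mm - 12.0) < 0.05
        assert f.conicity_mm < 0.05
        assert f.is_straight

    def test_cone_frustum_mean_diameter(self):
        # linear taper 20 mm (distal) -> 12 mm (proximal) over 80 mm
        p = CanalParams(length_mm=80.0, curvature_radius_mm=STRAIGHT,
                        diameter_distal_mm=20.0, diameter_min_mm=12.0,
                        z_min_frac=0.99, ellipticity_mm=0.0,
                        proximal_flare_mm=0.0, isthmus_plateau_mm=0.0)
        mesh = generate_canal(p, 64, 81)
        slices = extract_slices(mesh)
        stations = np.array([s.station for s in slices])
        analytic = 20.0 + (12.0 - 20.0) * stations / (0.99 * 80.0)
        f = compute_features(slices, mesh.extent)
        assert abs(f.mean_diameter_mm - analytic.mean()) / analytic.mean() < 0.01

    def test_conicity_never_negative(self):
        rng = np.random.default_rng(5)
        from canalssm import PopulationSpec, draw_params, unposed
        spec = PopulationSpec(seed=0)
        for _ in range(5):
            prm = unposed(draw_params(spec, rng))
            f = canal_features(generate_canal(prm, 32, 61))
            assert f.conicity_mm >= 0.0

    def test_rigid_motion_about_z_invariance(self, curved_mesh):
        base = canal_features(curved_mesh)
        T = RigidTransform.from_rotvec([0.0, 0.0, np.radians(40.0)], [8.0, -6.0, 0.0])
        moved = canal_features(curved_mesh.transformed(T))
        assert moved.length_mm == pytest.approx(base.length_mm, abs=1e-6)
        assert moved.curvature_radius_mm == pytest.approx(
            base.curvature_radius_mm, rel=1e-3)
        assert moved.ellipticity_mm == pytest.approx(base.ellipticity_mm, abs=0.01)
        assert moved.mean_diameter_mm == pytest.approx(
            base.mean_diameter_mm, abs=0.01)
        assert moved.conicity_mm == pytest.approx(base.conicity_mm, abs=0.01)
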