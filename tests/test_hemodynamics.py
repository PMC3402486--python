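import numpy as np
import pytest

from oftmech.hemodynamics import (LumenModel, compare_with_doppler,
                                  fit_ellipse, fit_ellipse_series, solve_flow,
                                  summarize, wss_field)
from oftmech.segmentation import Contour, ContourSeries

PHASES = np.arange(196) / 196.0
Z5 = np.linspace(0.0, 0.6, 5)


def _rigid_model(a, b, mu=3e-3):
    const_a = np.full((5, PHASES.size), a)
    const_b = np.full((5, PHASES.size), b)
    return LumenModel(z_mm=Z5, phases=PHASES, a_mm=const_a, b_mm=const_b,
                      angle_rad=np.zeros(5), mu_pa_s=mu, window_cycle=(0, 1))


def _moving_model():
    a = 0.15 + 0.03 * np.sin(2 * np.pi * PHASES)[None, :] \
        * np.linspace(1, 0.5, 5)[:, None]
    b = 0.10 + 0.015 * np.cos(2 * np.pi * PHASES)[None, :] \
        * np.linspace(0.8, 1, 5)[:, None]
    return LumenModel(z_mm=Z5, phases=PHASES, a_mm=a, b_mm=b,
                      angle_rad=np.linspace(0.2, 1.0, 5), window_cycle=(0, 1))


class TestClosedForms:
    def test_circular_poiseuille(self):
        R, dP, mu, L = 0.15, 10.0, 3e-3, 0.6
        sol = solve_flow(_rigid_model(R, R, mu), np.full(196, dP))
        exact = np.pi * R**4 * dP / (8 * mu * L)
        assert np.allclose(sol.Q_mm3_s, exact, rtol=1e-6)
        # centerline velocity of the parabolic profile
        assert np.allclose(sol.U0_mm_s, 2 * exact / (np.pi * R**2), rtol=1e-6)

    def test_elliptical_poiseuille(self):
        a, b, dP, mu, L = 0.2, 0.1, 10.0, 3e-3, 0.6
        sol = solve_flow(_rigid_model(a, b, mu), np.full(196, dP))
        exact = np.pi * a**3 * b**3 * dP / (4 * mu * (a**2 + b**2) * L)
        assert np.allclose(sol.Q_mm3_s, exact, rtol=1e-6)

    def test_zero_pressure_rigid_tube_no_flow(self):
        sol = solve_flow(_rigid_model(0.15, 0.12), np.zeros(196))
        assert np.allclose(sol.Q_mm3_s, 0.0, atol=1e-15)


class TestMovingWalls:
    def test_mass_conservation_analytic_geometry(self):
        sol = solve_flow(_moving_model(), 5 * np.sin(2 * np.pi * PHASES + 1),
                         n_steps=200, n_z=401)
        assert sol.mass_residual() < 1e-6

    def test_grid_convergence_peak_velocity(self):
        dp = 5 * np.sin(2 * np.pi * PHASES + 1)
        coarse = solve_flow(_moving_model(), dp, n_steps=100, n_z=101)
        fine = solve_flow(_moving_model(), dp, n_steps=200, n_z=201)
        p1 = np.max(np.abs(coarse.U0_mm_s))
        p2 = np.max(np.abs(fine.U0_mm_s))
        assert abs(p1 - p2) / p2 < 0.01

    def test_zero_dp_matches_dense_grid_oracle(self):
        # inlet flow balances the wall-motion source; a 10x denser axial
        # grid serves as the brute-force reference
        dp = np.zeros(196)
        sol = solve_flow(_moving_model(), dp, n_steps=60, n_z=101)
        dense = solve_flow(_moving_model(), dp, n_steps=60, n_z=1001)
        scale = np.max(np.abs(dense.Q0_mm3_s))
        assert np.max(np.abs(sol.Q0_mm3_s - dense.Q0_mm3_s)) / scale < 1e-3

    def test_closure_blocks_through_flow(self):
        m = _moving_model()
        b = m.b_mm.copy()
        b[-1, 90:110] = 0.0   # distal station pinches shut
        m2 = LumenModel(z_mm=m.z_mm, phases=m.phases, a_mm=m.a_mm, b_mm=b,
                        angle_rad=m.angle_rad, window_cycle=(0, 1))
        with pytest.warns(UserWarning):
            sol = solve_flow(m2, np.full(196, 5.0))
        closed_steps = sol.closed
        assert closed_steps.any()
        # no through-flow at the closed outlet
        assert np.all(np.abs(sol.Q_mm3_s[closed_steps, -1]) < 1e-12)


class TestWSS:
    def test_circular_duct_uniform_poiseuille_wss(self):
        R, dP, mu, L = 0.15, 10.0, 3e-3, 0.6
        model = _rigid_model(R, R, mu)
        sol = solve_flow(model, np.full(196, dP))
        tau, s = wss_field(sol, model, n_s=32)
        Q = sol.Q_mm3_s[0, 0]
        expected = 4 * mu * Q / (np.pi * R**3)
        np.testing.assert_allclose(tau[0, 0], expected, rtol=1e-9)

    def test_minor_axis_twice_major_axis_wss_for_2_to_1_ellipse(self):
        model = _rigid_model(0.2, 0.1)
        sol = solve_flow(model, np.full(196, 10.0))
        tau, s = wss_field(sol, model, n_s=64)
        minor = tau[0, 0, np.argmin(np.abs(s - np.pi / 2))]
        major = tau[0, 0, 0]
        assert minor / major == pytest.approx(2.0, rel=1e-6)

    def test_zero_flow_zero_wss(self):
        model = _rigid_model(0.2, 0.1)
        sol = solve_flow(model, np.zeros(196))
        tau, _ = wss_field(sol, model)
        assert np.nanmax(tau) == 0.0

    def test_maxima_on_minor_axis_every_open_step(self):
        model = _moving_model()
        sol = solve_flow(model, 5 + 3 * np.sin(2 * np.pi * PHASES))
        tau, s = wss_field(sol, model, n_s=64)
        k_minor = {np.argmin(np.abs(s - np.pi / 2)),
                   np.argmin(np.abs(s - 3 * np.pi / 2))}
        for i in range(0, sol.t_s.size, 20):
            for j in range(0, sol.z_mm.size, 25):
                if np.all(np.isnan(tau[i, j])):
                    continue
                assert int(np.nanargmax(tau[i, j])) in k_minor

    def test_spiral_ridge_recovers_orientation_rate(self):
        rate = 1.5  # rad per mm of cushion spiral
        m = _moving_model()
        m2 = LumenModel(z_mm=m.z_mm, phases=m.phases, a_mm=m.a_mm, b_mm=m.b_mm,
                        angle_rad=rate * m.z_mm, window_cycle=(0, 1))
        sol = solve_flow(m2, 5 + 3 * np.sin(2 * np.pi * PHASES))
        rep = summarize(sol, m2)
        assert rep["spiral_rate_rad_per_mm"] == pytest.approx(rate, rel=0.05)


class TestEllipseFits:
    def test_exact_ellipse_polygon_recovered(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([50 + 30 * np.cos(t) * np.cos(0.4)
                               - 18 * np.sin(t) * np.sin(0.4),
                               50 + 30 * np.cos(t) * np.sin(0.4)
                               + 18 * np.sin(t) * np.cos(0.4)])
        xc, yc, a, b, th = fit_ellipse(pts)
        assert (xc, yc) == pytest.approx((50, 50), abs=1e-6)
        assert a == pytest.approx(30, rel=1e-3)
        assert b == pytest.approx(18, rel=1e-3)
        assert th == pytest.approx(0.4, abs=1e-6)

    def test_circle_gives_equal_axes(self):
        t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t)])
        _, _, a, b, _ = fit_ellipse(pts)
        assert a == pytest.approx(b, rel=1e-6)

    def test_series_reports_area_error_and_closure(self):
        series = ContourSeries(plane_id=0, pixel_pitch_um=5.0)
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        open_c = Contour(vertices_px=np.column_stack(
            [64 + 20 * np.cos(t), 64 + 12 * np.sin(t)]),
            label="endo", frame=0)
        slit = Contour(vertices_px=np.column_stack(
            [64 + 15 * np.cos(t), 64 + 0.25 * np.sin(t)]),
            label="endo", frame=1, degenerate=True)
        series.add(open_c)
        series.add(slit)
        df = fit_ellipse_series(series)
        assert not df.loc[0, "closed"] and df.loc[0, "area_error"] < 0.005
        assert df.loc[1, "closed"] and df.loc[1, "b_mm"] == pytest.approx(1e-3)


class TestDopplerComparison:
    def test_solution_against_itself_is_exact(self):
        from oftmech.doppler import VelocitySeries

        model = _moving_model()
        sol = solve_flow(model, 5 + 3 * np.sin(2 * np.pi * PHASES))
        z = 0.3
        u = sol.centerline_velocity_at(z)
        series = VelocitySeries(
            times_s=sol.t_s, velocity_mm_s=np.abs(u), v_axial_mm_s=u,
            masked=np.zeros_like(u, bool), plateau=np.zeros_like(u, bool),
            theta_deg=65.0)
        rep = compare_with_doppler(sol, series, z)
        assert rep["relative_rms"] < 1e-9

    def test_flagged_samples_excluded(self):
        from oftmech.doppler import VelocitySeries

        model = _moving_model()
        sol = solve_flow(model, 5 + 3 * np.sin(2 * np.pi * PHASES))
        z = 0.3
        u = sol.centerline_velocity_at(z)
        corrupted = np.abs(u).copy()
        plateau = np.zeros_like(u, bool)
        plateau[60:80] = True
        corrupted[60:80] = 1e6   # must be ignored
        series = VelocitySeries(
            times_s=sol.t_s, velocity_mm_s=corrupted, v_axial_mm_s=u,
            masked=np.zeros_like(u, bool), plateau=plateau, theta_deg=65.0)
        rep = compare_with_doppler(sol, series, z)
        assert rep["relative_rms"] < 0.05

    def test_disjoint_supports_rejected(self):
        from oftmech.doppler import VelocitySeries

        model = _moving_model()
        sol = solve_flow(model, np.full(196, 5.0))
        series = VelocitySeries(
            times_s=sol.t_s, velocity_mm_s=np.ones_like(sol.t_s),
            v_axial_mm_s=np.ones_like(sol.t_s),
            masked=np.ones_like(sol.t_s, bool),
            plateau=np.zeros_like(sol.t_s, bool), theta_deg=65.0)
        with pytest.raises(ValueError):
            compare_with_doppler(sol, series, 0.3)
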