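import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oftmech import DopplerConfig
from oftmech.doppler import (angle_correct, centerline_velocity_series,
                             phase_to_velocity, unwrap_phase,
                             velocity_to_phase, wrap_phase)
from oftmech.phantom import render_doppler_phase
from oftmech.reconstruction import extract_mmode


class TestPhaseToVelocity:
    def test_pi_gives_detection_limit(self):
        v = phase_to_velocity(np.pi)
        assert v == pytest.approx(11.996, abs=5e-3)

    def test_zero_phase_zero_velocity(self):
        assert phase_to_velocity(0.0) == 0.0

    def test_half_pi_is_half_the_limit(self):
        assert phase_to_velocity(np.pi / 2) \
            == pytest.approx(phase_to_velocity(np.pi) / 2, rel=1e-12)

    @given(st.floats(-10, 10), st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity(self, phi, scale):
        assert phase_to_velocity(phi * scale) \
            == pytest.approx(scale * phase_to_velocity(phi), rel=1e-9,
                             abs=1e-12)

    def test_inverse_of_velocity_to_phase(self):
        cfg = DopplerConfig()
        v = np.linspace(-30, 30, 13)
        np.testing.assert_allclose(phase_to_velocity(velocity_to_phase(v, cfg),
                                                     cfg), v, atol=1e-12)


class TestAngleCorrect:
    def test_unwrapped_limit_at_plane2_angle(self):
        assert angle_correct(24.0, 58.4) == pytest.approx(45.8, abs=0.05)

    def test_zero_angle_identity(self):
        assert angle_correct(7.7, 0.0) == 7.7

    def test_large_angle_amplification(self):
        assert angle_correct(1.0, 84.0) == pytest.approx(9.567, abs=5e-3)

    def test_perpendicular_beam_rejected(self):
        with pytest.raises(ValueError):
            angle_correct(1.0, 90.0)


class TestUnwrap:
    def test_series_without_jumps_unchanged(self):
        phi = np.linspace(-2.0, 2.0, 50)
        np.testing.assert_allclose(unwrap_phase(phi), phi)

    def test_wrapped_ramp_recovered(self):
        true = np.linspace(0.0, 6 * np.pi, 200)
        rec = unwrap_phase(wrap_phase(true))
        np.testing.assert_allclose(rec, true, atol=1e-9)

    def test_single_jump_removed(self):
        phi = np.array([0.1, 0.2, 0.3 + 2 * np.pi, 0.4 + 2 * np.pi])
        rec = unwrap_phase(phi)
        np.testing.assert_allclose(np.diff(rec), 0.1, atol=1e-9)

    @given(st.lists(st.floats(-3.0, 3.0), min_size=3, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_wrap_unwrap_identity_below_pi_steps(self, steps):
        # any series whose true increments stay below pi survives the trip
        inc = np.clip(np.asarray(steps), -3.0, 3.0)
        true = np.concatenate([[0.0], np.cumsum(inc)])
        rec = unwrap_phase(wrap_phase(true))
        np.testing.assert_allclose(rec, true, atol=1e-7)

    def test_wrap_phase_range(self):
        x = np.linspace(-20, 20, 1001)
        w = wrap_phase(x)
        assert np.all(w > -np.pi) and np.all(w <= np.pi)


class TestCenterlineSeries:
    def _render(self, u0, theta, seed=7, noise=None):
        from oftmech import PhantomConfig

        kw = {} if noise is None else dict(phase_noise_sd_rad=noise)
        cfg = PhantomConfig(seed=seed, **kw).replace(
            doppler_angle_deg=(84.0, 58.4, theta, 70.0, 75.0))
        rng = np.random.default_rng(seed)
        phases = np.arange(u0.size) / u0.size
        stack = render_doppler_phase(u0, cfg, 2, rng=rng, frame_phases=phases)
        n = cfg.image_size_px
        c = (n - 1) / 2
        return extract_mmode(stack, ((0, c), (n - 1, c)), n_samples=n,
                             channel="phase"), n

    def test_zero_flow_within_noise_floor(self):
        u0 = np.zeros(48)
        mphase, n = self._render(u0, theta=65.0)
        vs = centerline_velocity_series(mphase, n // 2, theta_deg=65.0)
        assert np.nanmax(np.abs(vs.velocity_mm_s)) < 1.5

    def test_round_trip_below_wrap_limit(self):
        theta = 65.0
        limit = DopplerConfig().velocity_limit_mm_s
        phases = np.arange(196) / 196
        u0 = np.where((phases > 0.33) & (phases < 0.75),
                      0.8 * limit / np.cos(np.deg2rad(theta))
                      * np.sin(np.pi * (phases - 0.33) / 0.42) ** 2, 0.0)
        mphase, n = self._render(u0, theta)
        open_mask = u0 > 0.02 * u0.max()
        vs = centerline_velocity_series(mphase, n // 2, theta_deg=theta,
                                        open_mask=open_mask)
        est = np.abs(vs.velocity_mm_s)
        ok = vs.valid & np.isfinite(est)
        rms = np.sqrt(np.mean((est[ok] - u0[ok]) ** 2)) / u0.max()
        assert rms < 0.05

    def test_plateau_flagged_beyond_doubled_limit(self):
        theta = 58.4
        limit = DopplerConfig().velocity_limit_mm_s
        phases = np.arange(196) / 196
        # axial velocity peaks at 2.5x the single-pass limit
        vpeak = 2.5 * limit / np.cos(np.deg2rad(theta))
        u0 = np.where((phases > 0.3) & (phases < 0.8),
                      vpeak * np.sin(np.pi * (phases - 0.3) / 0.5) ** 2, 0.0)
        mphase, n = self._render(u0, theta)
        open_mask = u0 > 0.02 * u0.max()
        with pytest.warns(UserWarning):
            vs = centerline_velocity_series(mphase, n // 2, theta_deg=theta,
                                            open_mask=open_mask)
        assert vs.plateau.sum() > 0
        # reported velocities saturate at the doubled limit
        assert np.nanmax(np.abs(vs.v_axial_mm_s)) \
            <= 2 * limit + 1e-9

    def test_closed_frames_reported_missing(self):
        u0 = np.zeros(32)
        mphase, n = self._render(u0, theta=65.0)
        open_mask = np.zeros(32, dtype=bool)
        open_mask[10:20] = True
        vs = centerline_velocity_series(mphase, n // 2, theta_deg=65.0,
                                        open_mask=open_mask)
        assert np.all(np.isnan(vs.velocity_mm_s[~open_mask]))
        assert np.all(np.isfinite(vs.velocity_mm_s[open_mask]))

    def test_row_outside_raster_rejected(self):
        with pytest.raises(ValueError):
            centerline_velocity_series(np.zeros((8, 10)), 9)
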