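import numpy as np
import pytest

from oftmech import (DopplerConfig, PhantomConfig, generate_geometry,
                     generate_pressure_traces, render_sequences, wrap_phase)
from oftmech.doppler import velocity_to_phase
from oftmech.phantom import closure_onset_phase, render_doppler_phase


class TestGeometry:
    def test_expanded_lumen_near_circular(self):
        cfg = PhantomConfig()
        g = generate_geometry(cfg, 0.0, 0.5 * cfg.period_s)
        assert g.open
        assert 1.0 <= g.shape_factor <= 1.2

    def test_no_cushions_gives_inner_circle(self):
        # degenerate cushion case: no jelly margin and jelly fully displaced
        # at expansion leaves the lumen equal to the inner myocardial circle
        cfg = PhantomConfig(jelly_margin_mm=0.0, jelly_asf=1.0)
        g = generate_geometry(cfg, 0.0, 0.5 * cfg.period_s)
        assert g.a_mm == pytest.approx(g.r_inner_mm, rel=1e-9)
        assert g.b_mm == pytest.approx(g.r_inner_mm, rel=1e-9)

    def test_closure_onset_propagates_distally(self):
        cfg = PhantomConfig()
        dt_cycles = closure_onset_phase(cfg, cfg.tube_length_um) \
            - closure_onset_phase(cfg, 0.0)
        expected = cfg.tube_length_um / (cfg.peristaltic_wave_speed_um_s
                                         * cfg.period_s)
        assert dt_cycles == pytest.approx(expected, abs=1e-9)

    def test_z_out_of_range_raises(self):
        with pytest.raises(ValueError):
            generate_geometry(PhantomConfig(), -1.0, 0.0)

    def test_lumen_closed_on_plateau(self):
        g = generate_geometry(PhantomConfig(), 0.0, 0.0)
        assert not g.open
        assert g.lumen_area_mm2 == 0.0

    def test_invariants_validated(self):
        with pytest.raises(ValueError):
            PhantomConfig(r_inner_max_mm=(0.15, 0.17, 0.19, 0.20, 0.21)).validate()
        with pytest.raises(ValueError):
            PhantomConfig(period_s=-1.0).validate()


class TestRendering:
    def test_fixed_seed_bitwise_identical(self):
        cfg = PhantomConfig.with_n_planes(2, image_size_px=64, n_cycles=2, seed=9)
        s1, t1 = render_sequences(cfg, n_phases=48)
        s2, t2 = render_sequences(cfg, n_phases=48)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.frames, b.frames)
            assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(t1.start_phase, t2.start_phase)
        assert np.array_equal(t1.p_vent.pressure_pa, t2.p_vent.pressure_pa)

    def test_noiseless_layers_and_boundaries(self):
        cfg = PhantomConfig.with_n_planes(
            2, speckle_contrast=0.0, phase_noise_sd_rad=0.0,
            attenuation_per_mm=0.0, n_cycles=2, seed=0)
        seqs, truth = render_sequences(cfg, include_doppler=False, n_phases=48)
        frames = seqs[0].frames
        # piecewise-constant intensity: only the four layer levels appear
        levels = np.unique(frames).astype(np.float64)
        expected = {cfg.intensity_background, cfg.intensity_myocardium,
                    cfg.intensity_jelly, cfg.intensity_lumen}
        assert {round(v, 4) for v in levels} <= {round(v, 4) for v in expected}
        # rendered lumen boundary within one pixel of the truth ellipse
        ph = truth.frame_phase(0, np.arange(seqs[0].n_frames))
        k = int(np.argmin(np.abs(ph - 0.5)))
        g = truth.geometry_at(0, ph[k])
        n = cfg.image_size_px
        idx = (np.arange(n) - (n - 1) / 2) * cfg.pixel_pitch_um * 1e-3
        x, y = np.meshgrid(idx, idx)
        lum = frames[k] == np.float32(cfg.intensity_lumen)
        c, s = np.cos(g.angle_rad), np.sin(g.angle_rad)
        u, v = x * c + y * s, -x * s + y * c
        e = np.sqrt((u / g.a_mm) ** 2 + (v / g.b_mm) ** 2)
        # boundary pixels of the rendered mask sit at e ~ 1
        border = lum & ~np.roll(lum, 1, 0) | lum & ~np.roll(lum, 1, 1)
        tol = cfg.pixel_pitch_um * 1e-3 / g.b_mm  # one pixel in ellipse units
        assert np.all(np.abs(e[border] - 1.0) < 2 * tol)

    def test_start_phases_recorded_match_rendering(self, phantom_default):
        seqs, truth = phantom_default
        cfg = truth.config
        for i, seq in enumerate(seqs):
            # the central lumen-proxy is minimal at the closed plateau,
            # whose centre frame is predicted by the recorded phase offsets
            proxy = seq.frames[:, 60:68, 60:68].mean(axis=(1, 2))
            ph = truth.frame_phase(i, np.arange(seq.n_frames))
            plateau_phase = np.mod(truth.wave_delay_cycles[i], 1.0)
            dist = np.abs(np.mod(ph - plateau_phase + 0.5, 1.0) - 0.5)
            closed = dist < 0.5 - cfg.open_duty / 2 - 0.02
            assert proxy[closed].mean() < proxy[~closed].mean()

    def test_all_planes_closed_fraction_near_half(self, phantom_default):
        _, truth = phantom_default
        frac = truth.closure_fraction_all_planes()
        assert abs(frac - truth.config.closure_fraction_target) \
            <= 0.1 * truth.config.closure_fraction_target


class TestPressure:
    def test_default_peaks_match_configured_values(self):
        vent, aos = generate_pressure_traces(PhantomConfig())
        assert vent.peak_pa == pytest.approx(196.0, abs=1e-9)
        assert aos.peak_pa == pytest.approx(180.0, abs=1e-9)
        assert vent.peak_pa >= aos.peak_pa
        assert vent.sampling_rate_hz == 100.0

    def test_equal_peaks_zero_driving_pressure(self):
        cfg = PhantomConfig(p_vent_peak_pa=150.0, p_as_peak_pa=150.0,
                            p_vent_width_cycle=0.5, p_as_width_cycle=0.5,
                            p_vent_dia_pa=30.0, p_as_dia_pa=30.0)
        vent, aos = generate_pressure_traces(cfg)
        i = int(np.argmax(vent.pressure_pa))
        assert vent.pressure_pa[i] - aos.pressure_pa[i] == pytest.approx(0.0, abs=1e-9)

    def test_periodicity(self):
        cfg = PhantomConfig()
        vent, _ = generate_pressure_traces(cfg)
        # one-period autocovariance peak at the cardiac period
        p = vent.pressure_pa - vent.pressure_pa.mean()
        ac = np.correlate(p, p, "full")[p.size - 1:]
        lag = int(round(cfg.period_s * cfg.pressure_rate_hz))
        assert ac[lag] > 0.8 * ac[0] * (1 - lag / p.size)


class TestDopplerRendering:
    def test_zero_flow_noise_only(self):
        cfg = PhantomConfig(phase_noise_sd_rad=0.0)
        u0 = np.zeros(48)
        stack = render_doppler_phase(u0, cfg, 0, frame_phases=np.arange(48) / 48)
        assert np.allclose(stack, 0.0)

    def test_wrap_limit_at_pi(self):
        dcfg = DopplerConfig()
        assert velocity_to_phase(dcfg.velocity_limit_mm_s, dcfg) \
            == pytest.approx(np.pi, rel=1e-12)

    def test_beyond_limit_wraps_negative(self):
        dcfg = DopplerConfig()
        phi = velocity_to_phase(18.0, dcfg)        # > pi
        assert wrap_phase(phi) == pytest.approx(phi - 2 * np.pi, rel=1e-12)

    def test_rendered_phase_in_range(self, phantom_default):
        cfg = PhantomConfig(seed=4)
        u0 = np.full(32, 30.0)
        rng = np.random.default_rng(0)
        stack = render_doppler_phase(u0, cfg, 1, rng=rng,
                                     frame_phases=np.arange(32) / 32)
        assert stack.max() <= np.pi and stack.min() > -np.pi
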