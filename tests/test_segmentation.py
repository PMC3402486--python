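import numpy as np
import pytest

from oftmech import PhantomConfig, render_sequences
from oftmech.segmentation import (Centerline, Contour, compute_centerline,
                                  propagate_contours, segment_frame,
                                  select_cross_sections)


def _circle(radius_px, n=64, center=(63.5, 63.5)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius_px * np.cos(t),
                            center[1] + radius_px * np.sin(t)])


def _truth_areas(truth, plane, phases):
    lum, inner, outer = [], [], []
    for p in phases:
        g = truth.geometry_at(plane, p)
        lum.append(g.lumen_area_mm2)
        inner.append(np.pi * g.r_inner_mm**2)
        outer.append(np.pi * g.r_outer_mm**2)
    return np.array(lum), np.array(inner), np.array(outer)


class TestContour:
    def test_orientation_forced_ccw(self):
        cw = _circle(10)[::-1]
        c = Contour(vertices_px=cw, label="endo")
        x, y = c.vertices_px[:, 0], c.vertices_px[:, 1]
        assert 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) > 0

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            Contour(vertices_px=np.zeros((2, 2)), label="endo")

    def test_resampling_preserves_geometry(self):
        c = Contour(vertices_px=_circle(20, n=64), label="endo")
        c2 = c.resample(128)
        assert abs(c2.area_mm2 - c.area_mm2) / c.area_mm2 < 1e-3
        assert abs(c2.perimeter_mm - c.perimeter_mm) / c.perimeter_mm < 1e-3

    def test_circle_area_and_perimeter(self):
        c = Contour(vertices_px=_circle(20, n=256), label="endo",
                    pixel_pitch_um=5.0)
        r_mm = 20 * 5e-3
        assert c.area_mm2 == pytest.approx(np.pi * r_mm**2, rel=2e-4)
        assert c.perimeter_mm == pytest.approx(2 * np.pi * r_mm, rel=2e-4)


class TestSegmentFrame:
    def test_perfect_annulus_recovers_radii(self):
        n = 128
        idx = np.arange(n) - (n - 1) / 2
        r = np.hypot(idx[None, :], idx[:, None])
        img = np.where((r > 25) & (r <= 45), 0.9, 0.05)
        outer = segment_frame(img, label="myo_outer")
        inner = segment_frame(img, label="myo_inner")
        r_out = np.hypot(*(outer.vertices_px - outer.centroid_px).T)
        r_in = np.hypot(*(inner.vertices_px - inner.centroid_px).T)
        assert np.median(r_out) == pytest.approx(45, abs=1.0)
        assert np.median(r_in) == pytest.approx(25, abs=1.0)

    def test_noiseless_inner_area_within_two_percent(self):
        cfg = PhantomConfig.with_n_planes(
            2, speckle_contrast=0.0, phase_noise_sd_rad=0.0, n_cycles=2, seed=0)
        seqs, truth = render_sequences(cfg, include_doppler=False, n_phases=48)
        ph = truth.frame_phase(0, np.arange(seqs[0].n_frames))
        k = int(np.argmin(np.abs(ph - 0.5)))
        c = segment_frame(seqs[0].frames[k], label="myo_inner",
                          pixel_pitch_um=cfg.pixel_pitch_um)
        g = truth.geometry_at(0, ph[k])
        true = np.pi * g.r_inner_mm**2
        assert abs(c.area_mm2 - true) / true < 0.02

    def test_default_noise_endo_dice(self, phantom_default):
        from matplotlib.path import Path as MPath

        seqs, truth = phantom_default
        cfg = truth.config
        ph = truth.frame_phase(0, np.arange(seqs[0].n_frames))
        k = int(np.argmin(np.abs(ph - 0.5)))
        c = segment_frame(seqs[0].frames[k], label="endo",
                          pixel_pitch_um=cfg.pixel_pitch_um)
        g = truth.geometry_at(0, ph[k])
        n = cfg.image_size_px
        yy, xx = np.mgrid[0:n, 0:n]
        seg = MPath(c.vertices_px).contains_points(
            np.column_stack([xx.ravel(), yy.ravel()])).reshape(n, n)
        idx = (np.arange(n) - (n - 1) / 2) * cfg.pixel_pitch_um * 1e-3
        x, y = np.meshgrid(idx, idx)
        cs, sn = np.cos(g.angle_rad), np.sin(g.angle_rad)
        u, v = x * cs + y * sn, -x * sn + y * cs
        true = (u / g.a_mm) ** 2 + (v / g.b_mm) ** 2 <= 1
        dice = 2 * np.sum(seg & true) / (seg.sum() + true.sum())
        assert dice >= 0.9

    def test_closed_lumen_returns_degenerate_slit(self, phantom_default):
        seqs, truth = phantom_default
        ph = truth.frame_phase(0, np.arange(seqs[0].n_frames))
        k = int(np.argmin(np.abs(ph - 0.02)))
        c = segment_frame(seqs[0].frames[k], label="endo")
        assert c.degenerate
        assert c.area_mm2 < 0.002

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            segment_frame(np.zeros((32, 32)), label="lumen")


class TestPropagation:
    def test_static_sequence_identical_contours(self, phantom_default):
        seqs, truth = phantom_default
        ph = truth.frame_phase(0, np.arange(seqs[0].n_frames))
        k = int(np.argmin(np.abs(ph - 0.5)))
        static = np.repeat(seqs[0].frames[k][None], 4, axis=0)
        series = propagate_contours(static, labels=("myo_inner",))
        areas = series.areas_mm2("myo_inner")
        assert np.ptp(areas) / areas.mean() < 1e-3

    def test_full_cycle_areas_within_five_percent(self, phantom_default):
        seqs, truth = phantom_default
        cfg = truth.config
        nf = int(np.ceil(cfg.period_frames)) + 1
        for plane in (0, 4):   # proximal and the hardest (thin-ring) plane
            series = propagate_contours(seqs[plane].frames[:nf],
                                        plane_id=plane,
                                        pixel_pitch_um=cfg.pixel_pitch_um)
            ph = truth.frame_phase(plane, np.arange(nf))
            lum, inner, outer = _truth_areas(truth, plane, ph)
            for label, true in (("endo", lum), ("myo_inner", inner),
                                ("myo_outer", outer)):
                est = series.areas_mm2(label)
                err = np.abs(est - true) / true.max()
                assert err.max() <= 0.05, f"plane {plane} {label}"
            assert series.check_nesting()

    def test_recovery_after_corrupted_frame(self, phantom_default):
        seqs, truth = phantom_default
        cfg = truth.config
        ph = truth.frame_phase(0, np.arange(seqs[0].n_frames))
        k = int(np.argmin(np.abs(ph - 0.5)))
        frames = seqs[0].frames[k:k + 6].copy()
        rng = np.random.default_rng(0)
        frames[2] = rng.uniform(0, 1, frames[2].shape)  # destroyed frame
        series = propagate_contours(frames, labels=("myo_inner",),
                                    pixel_pitch_um=cfg.pixel_pitch_um)
        areas = series.areas_mm2("myo_inner")
        true = np.pi * truth.geometry_at(0, ph[k + 4]).r_inner_mm**2
        assert abs(areas[4] - true) / true < 0.05


class TestCenterline:
    def _sections(self, cfg, offset=(0.0, 0.0)):
        sections = []
        for i, z in enumerate(cfg.z_planes_um):
            r_px = cfg.r_inner_min_mm[i] / (cfg.pixel_pitch_um * 1e-3)
            center = (63.5 + offset[0], 63.5 + offset[1])
            sections.append((float(z), Contour(
                vertices_px=_circle(r_px, center=center),
                label="myo_inner", plane_id=i,
                pixel_pitch_um=cfg.pixel_pitch_um)))
        return sections

    def test_straight_phantom_arc_length(self):
        cfg = PhantomConfig()
        cl = compute_centerline(self._sections(cfg))
        assert cl.arc_length_mm == pytest.approx(0.6, abs=5e-3)

    def test_translation_equivariance(self):
        cfg = PhantomConfig()
        cl0 = compute_centerline(self._sections(cfg))
        cl1 = compute_centerline(self._sections(cfg, offset=(10.0, -6.0)))
        shift = cl1.points_mm[:, :2] - cl0.points_mm[:, :2]
        np.testing.assert_allclose(shift[:, 0], 10 * 5e-3, atol=1e-9)
        np.testing.assert_allclose(shift[:, 1], -6 * 5e-3, atol=1e-9)

    def test_select_sections_spacing_and_normals(self):
        cfg = PhantomConfig()
        cl = compute_centerline(self._sections(cfg))
        secs = select_cross_sections(cl, n=5)
        pts = np.array([p for p, _ in secs])
        spacing = np.diff(pts[:, 2])
        np.testing.assert_allclose(spacing, 0.15, atol=5e-3)
        axis = np.array([0.0, 0.0, 1.0])
        for _, normal in secs:
            angle = np.degrees(np.arccos(abs(normal @ axis)))
            assert angle < 10.0

    def test_two_points_gives_endpoints(self):
        cl = Centerline(points_mm=np.column_stack([np.zeros(10), np.zeros(10),
                                                   np.linspace(0, 1, 10)]),
                        arc_length_mm=1.0,
                        tangents=np.tile([0, 0, 1.0], (10, 1)))
        secs = select_cross_sections(cl, n=2)
        assert secs[0][0][2] == pytest.approx(0.0)
        assert secs[1][0][2] == pytest.approx(1.0)

    def test_single_plane_rejected(self):
        cfg = PhantomConfig()
        with pytest.raises(ValueError):
            compute_centerline(self._sections(cfg)[:1])
        with pytest.raises(ValueError):
            select_cross_sections(compute_centerline(self._sections(cfg)), n=1)
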