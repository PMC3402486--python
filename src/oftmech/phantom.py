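"""Synthetic 4D-OCT phantom of the embryonic outflow tract (OFT).

The phantom renders per-plane cross-sectional image sequences of a tapered,
peristaltically contracting tube with the layer structure of the HH18 chick
OFT wall: a bright myocardial ring, a dark cardiac-jelly layer whose two
opposed lobes (endocardial cushions) spiral along the tube, and a mid-level
lumen that is indistinguishable in intensity from the endocardium.  Every
rendered quantity is also returned analytically as ground truth, so each
analysis stage can be validated by parameter recovery.

Geometry model
--------------
At axial position ``z`` and cardiac phase ``phi`` (cycle fraction), the inner
myocardial radius follows a raised-cosine activation pulse delayed linearly in
``z`` (peristalsis)::

    w(phi)   = cos^2(pi (phi - 0.5) / d)   on |phi - 0.5| < d/2, else 0
    R(z,phi) = R_min(z) + (R_max(z) - R_min(z)) * w(phi - delta(z))

with ``d`` the open duty cycle and ``delta(z) = z / (c T)`` the peristaltic
delay at wave speed ``c``.  The cardiac-jelly cross-sectional area shrinks
with expansion (the jelly redistributes longitudinally as the tube stretches),

    A_jelly(z,phi) = pi R_min(z)^2 (1 - jelly_asf * w),

so the lumen area ``A = pi R^2 - A_jelly`` vanishes exactly on the closed
plateau (w = 0) and opens smoothly.  The open lumen is an ellipse whose major
semi-axis spans the inner circle up to a thin jelly margin and whose minor
axis is set by the area; at full contraction the lumen degenerates to a slit
along the major axis, mimicking the apposition of the cushions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import DopplerConfig, PhantomConfig
from .doppler import velocity_to_phase, wrap_phase

__all__ = [
    "CrossSection",
    "ImageSequence",
    "GroundTruth",
    "generate_geometry",
    "generate_pressure_traces",
    "render_sequences",
    "render_doppler_phase",
    "activation_pulse",
    "closure_onset_phase",
]


def activation_pulse(phi: np.ndarray | float, duty: float) -> np.ndarray:
    """Raised-cosine radial activation, 1 at mid-expansion, 0 on the closed plateau."""
    u = np.mod(np.asarray(phi, dtype=float), 1.0) - 0.5
    w = np.where(np.abs(u) < duty / 2.0, np.cos(np.pi * u / duty) ** 2, 0.0)
    return w


@dataclass(frozen=True)
class CrossSection:
    """Analytic description of one cross-section at one instant."""

    z_um: float
    phase: float
    r_inner_mm: float
    r_outer_mm: float
    lumen_area_mm2: float
    jelly_area_mm2: float
    a_mm: float            # lumen semi-major axis (slit half-length when closed)
    b_mm: float            # lumen semi-minor axis (0 when closed)
    angle_rad: float       # orientation of the major axis in the image plane
    open: bool

    @property
    def shape_factor(self) -> float:
        return self.a_mm / self.b_mm if self.b_mm > 0 else np.inf


def _plane_params(config: PhantomConfig, z_um: float) -> tuple[float, float, float, float]:
    """Linearly interpolate per-plane radii/thickness defaults to arbitrary z."""
    z = config.z_planes_um
    rmax = float(np.interp(z_um, z, config.r_inner_max_mm))
    rmin = float(np.interp(z_um, z, config.r_inner_min_mm))
    h = float(np.interp(z_um, z, config.myo_thickness_mm))
    delta = z_um / (config.peristaltic_wave_speed_um_s * config.period_s)
    return rmax, rmin, h, delta


def _lumen_axes(config: PhantomConfig, rmin: float, r_in: np.ndarray,
                area: np.ndarray, open_mask: np.ndarray):
    """Ellipse axes from lumen area: major spans the inner circle minus the
    jelly margin; minor set by the area; near-circular states are clamped so
    that a >= b."""
    a = np.maximum(r_in - config.jelly_margin_mm, 1e-6)
    b = np.where(open_mask, area / (np.pi * a), 0.0)
    circ = b > a
    if np.any(circ):
        r_eq = np.sqrt(np.maximum(area, 0.0) / np.pi)
        a = np.where(circ, r_eq, a)
        b = np.where(circ, r_eq, b)
    # closed: slit of half-length set by the contracted inner circle
    a = np.where(open_mask, a, max(rmin - config.jelly_margin_mm, 1e-6))
    return a, b


def _geometry_arrays(config: PhantomConfig, z_um: float, phase: np.ndarray):
    rmax, rmin, h, delta = _plane_params(config, z_um)
    w = activation_pulse(np.asarray(phase) - delta, config.open_duty)
    r_in = rmin + (rmax - rmin) * w
    # myocardial cross-sectional area conserved during contraction
    r_out = np.sqrt(r_in**2 + 2.0 * rmax * h + h**2)
    a_jelly = np.pi * rmin**2 * (1.0 - config.jelly_asf * w)
    a_lumen = np.maximum(np.pi * r_in**2 - a_jelly, 0.0)
    open_mask = w > 0.0
    a, b = _lumen_axes(config, rmin, r_in, a_lumen, open_mask)
    angle = np.deg2rad(config.cushion_angle0_deg
                       + config.cushion_spiral_rate_deg_per_um * z_um) + np.pi / 2.0
    return r_in, r_out, a_lumen, a_jelly, a, b, angle, open_mask


def generate_geometry(config: PhantomConfig, z_um: float, t_s: float) -> CrossSection:
    """Analytic cross-section of the phantom at axial position ``z_um``, time ``t_s``.

    Raises ``ValueError`` if ``z_um`` lies outside the tube.
    """
    config.validate()
    if not 0.0 <= z_um <= config.tube_length_um:
        raise ValueError(f"z={z_um} um outside tube [0, {config.tube_length_um}]")
    phase = np.mod(t_s / config.period_s, 1.0)
    r_in, r_out, a_lum, a_jel, a, b, angle, open_mask = _geometry_arrays(
        config, z_um, np.asarray(phase))
    return CrossSection(
        z_um=z_um, phase=float(phase),
        r_inner_mm=float(r_in), r_outer_mm=float(r_out),
        lumen_area_mm2=float(a_lum), jelly_area_mm2=float(a_jel),
        a_mm=float(a), b_mm=float(b), angle_rad=float(angle),
        open=bool(open_mask),
    )


def closure_onset_phase(config: PhantomConfig, z_um: float) -> float:
    """Cycle phase at which the lumen at ``z_um`` closes (falling edge of the pulse)."""
    _, _, _, delta = _plane_params(config, z_um)
    return float(np.mod(0.5 + config.open_duty / 2.0 + delta, 1.0))


# ---------------------------------------------------------------------------
# image sequences


@dataclass
class ImageSequence:
    """One fixed plane's time-ordered raster stack.

    ``frames`` is (time, rows, cols) intensity in [0, 1]; ``phase`` is the
    optional Doppler phase channel in (-pi, pi].  The OCT beam runs along
    ``beam_axis`` (rows by default), which is the direction of depth
    attenuation and of the measured axial velocity component.
    """

    frames: np.ndarray
    pixel_pitch_um: float
    frame_rate_hz: float
    plane_id: int
    phase: np.ndarray | None = None
    beam_axis: int = 0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, rows, cols)")
        if self.phase is not None and self.phase.shape != self.frames.shape:
            raise ValueError("phase channel shape must match intensity frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class GroundTruth:
    """Everything the phantom was rendered from, for parameter-recovery tests.

    Canonical arrays are sampled on ``phases`` (cycle fractions, phase 0 at
    the centre of plane 1's closed plateau); per-plane rows are ordered
    proximal to distal.  ``lag_frames[i]`` is the phase lag of plane ``i``'s
    rendered activity relative to plane 0, in frames — the quantity the
    reconstruction stage estimates from the images.
    """

    config: PhantomConfig
    start_phase: np.ndarray          # (n_planes,) uniform random acquisition phase
    wave_delay_cycles: np.ndarray    # (n_planes,) peristaltic delay
    lag_frames: np.ndarray           # (n_planes,) observed activity lag vs plane 0
    phases: np.ndarray               # (n_phases,) canonical grid
    r_inner_mm: np.ndarray           # (n_planes, n_phases)
    r_outer_mm: np.ndarray
    lumen_area_mm2: np.ndarray
    jelly_area_mm2: np.ndarray
    a_mm: np.ndarray
    b_mm: np.ndarray
    angle_rad: np.ndarray            # (n_planes,)
    open_mask: np.ndarray            # (n_planes, n_phases) bool
    p_vent: "object" = None          # PressureTrace
    p_as: "object" = None
    p_vent_phase: np.ndarray | None = None   # on the canonical grid
    p_as_phase: np.ndarray | None = None
    flow: "object" = None            # FlowSolution on the open window
    centerline_velocity_mm_s: np.ndarray | None = None  # (n_planes, n_phases)

    def frame_phase(self, plane: int, k: np.ndarray | int) -> np.ndarray:
        """Cardiac phase of frame ``k`` of plane ``plane``."""
        pf = self.config.period_frames
        return np.mod(np.asarray(k) / pf + self.start_phase[plane], 1.0)

    def geometry_at(self, plane: int, phase: float) -> CrossSection:
        return generate_geometry(self.config, float(self.config.z_planes_um[plane]),
                                 float(phase) * self.config.period_s)

    def lumen_contour(self, plane: int, phase: float, n: int = 64) -> np.ndarray:
        """Ground-truth lumen boundary (mm, image coordinates) at one phase."""
        g = self.geometry_at(plane, phase)
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        c, s = np.cos(g.angle_rad), np.sin(g.angle_rad)
        b = max(g.b_mm, 1e-6)
        x = g.a_mm * np.cos(t) * c - b * np.sin(t) * s
        y = g.a_mm * np.cos(t) * s + b * np.sin(t) * c
        return np.column_stack([x, y])

    def closure_fraction_all_planes(self) -> float:
        """Fraction of the cycle during which every plane's lumen is closed."""
        return float(np.mean(~np.any(self.open_mask, axis=0)))


def _render_intensity_frame(config: PhantomConfig, z_um: float, phase: float,
                            x: np.ndarray, y: np.ndarray, r: np.ndarray,
                            atten: np.ndarray, rng: np.random.Generator | None
                            ) -> np.ndarray:
    r_in, r_out, _, _, a, b, angle, open_mask = _geometry_arrays(
        config, z_um, np.asarray(phase))
    img = np.full(x.shape, config.intensity_background, dtype=np.float64)
    img[r <= r_out] = config.intensity_myocardium
    img[r <= r_in] = config.intensity_jelly
    if open_mask and b > 0:
        c, s = np.cos(angle), np.sin(angle)
        u = x * c + y * s
        v = -x * s + y * c
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = config.intensity_lumen
    img = img * atten
    if rng is not None and config.speckle_contrast > 0:
        k = 1.0 / config.speckle_contrast**2
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _pixel_grid(config: PhantomConfig):
    n = config.image_size_px
    idx = (np.arange(n) - (n - 1) / 2.0) * config.pixel_pitch_um * 1e-3  # mm
    x = idx[np.newaxis, :] * np.ones((n, 1))
    y = idx[:, np.newaxis] * np.ones((1, n))
    r = np.hypot(x, y)
    depth_mm = np.arange(n)[:, np.newaxis] * config.pixel_pitch_um * 1e-3
    atten = np.exp(-config.attenuation_per_mm * depth_mm) * np.ones((1, n))
    return x, y, r, atten


def generate_pressure_traces(config: PhantomConfig, start_phase: float = 0.0):
    """Ventricular and aortic-sac pressure pulses at the configured peaks.

    Both traces are smooth periodic pulses at the cardiac frequency, sampled
    at ``pressure_rate_hz`` (100 Hz by default) over ``pressure_n_cycles``
    cycles, peaking at phase 0.5 of the canonical cycle — i.e. at maximal
    lumen expansion of the proximal plane.  The ventricular pulse is wider
    than the aortic-sac pulse so the driving pressure difference is positive
    throughout the ejection window.  Sampled maxima equal the configured peak
    values exactly.
    """
    from .wall_stress import PressureTrace

    fs = config.pressure_rate_hz
    n = int(np.ceil(config.pressure_n_cycles * config.period_s * fs))
    t = np.arange(n) / fs
    phi = np.mod(t / config.period_s + start_phase, 1.0)

    def _trace(peak, dia, width, site):
        p = dia + (peak - dia) * activation_pulse(phi, width)
        pmax = p.max()
        if pmax > dia:  # rescale so the sampled maximum hits the peak exactly
            p = dia + (p - dia) * (peak - dia) / (pmax - dia)
        return PressureTrace(time_s=t, pressure_pa=p, site=site, sampling_rate_hz=fs)

    vent = _trace(config.p_vent_peak_pa, config.p_vent_dia_pa,
                  config.p_vent_width_cycle, "ventricle")
    aos = _trace(config.p_as_peak_pa, config.p_as_dia_pa,
                 config.p_as_width_cycle, "aortic_sac")
    return vent, aos


def _pressure_on_phases(config: PhantomConfig, phases: np.ndarray):
    pv = config.p_vent_dia_pa + (config.p_vent_peak_pa - config.p_vent_dia_pa) \
        * activation_pulse(phases, config.p_vent_width_cycle)
    pa = config.p_as_dia_pa + (config.p_as_peak_pa - config.p_as_dia_pa) \
        * activation_pulse(phases, config.p_as_width_cycle)
    return pv, pa


def _true_flow(config: PhantomConfig, truth: GroundTruth, flow_cfg=None):
    """Solve the reduced-order flow model on the analytic geometry."""
    from .config import FlowConfig
    from .hemodynamics import LumenModel, solve_flow

    flow_cfg = flow_cfg or FlowConfig()
    model = LumenModel(
        z_mm=config.z_planes_um * 1e-3,
        phases=truth.phases,
        a_mm=truth.a_mm,
        b_mm=truth.b_mm,
        angle_rad=np.full(config.n_planes, np.nan) if truth.angle_rad is None
        else truth.angle_rad,
        period_s=config.period_s,
        mu_pa_s=flow_cfg.mu_pa_s,
        window_cycle=flow_cfg.window_cycle,
        b_floor_mm=flow_cfg.b_floor_mm,
    )
    if flow_cfg.auto_window:
        model = model.with_auto_window()
    dp = truth.p_vent_phase - truth.p_as_phase
    sol = solve_flow(model, dp, n_steps=flow_cfg.n_steps, n_z=flow_cfg.n_z)
    # centerline velocity per plane on the canonical phase grid
    u = np.zeros((config.n_planes, truth.phases.size))
    sol_phase = np.mod(sol.t_s / config.period_s, 1.0)
    order = np.argsort(sol_phase)
    for i, z in enumerate(config.z_planes_um * 1e-3):
        ui = sol.centerline_velocity_at(z)
        u[i] = np.interp(truth.phases, sol_phase[order], ui[order],
                         left=0.0, right=0.0)
    return sol, u


def render_doppler_phase(u0_of_phase: np.ndarray, config: PhantomConfig,
                         plane_id: int, doppler: DopplerConfig | None = None,
                         rng: np.random.Generator | None = None,
                         frame_phases: np.ndarray | None = None) -> np.ndarray:
    """Render the wrapped Doppler phase channel for one plane.

    ``u0_of_phase`` is the centerline (peak parabolic-profile) velocity in
    mm/s on the canonical phase grid of the ground truth.  The in-plane
    velocity profile is the elliptical Poiseuille profile scaled to that
    centerline value; its projection onto the beam axis through the Doppler
    angle gives the axial velocity, converted to inter-A-scan phase and
    wrapped into (-pi, pi].  Pixels outside the lumen carry zero-mean phase
    noise only.
    """
    doppler = doppler or DopplerConfig()
    x, y, _, _ = _pixel_grid(config)
    z_um = float(config.z_planes_um[plane_id])
    theta = np.deg2rad(config.doppler_angle_deg[plane_id])
    n_ph = u0_of_phase.shape[0]
    if frame_phases is None:
        frame_phases = np.arange(n_ph) / n_ph
    out = np.empty((len(frame_phases),) + x.shape, dtype=np.float32)
    grid = np.arange(n_ph) / n_ph
    for k, phi in enumerate(frame_phases):
        _, _, _, _, a, b, angle, open_mask = _geometry_arrays(
            config, z_um, np.asarray(phi))
        phase_img = np.zeros(x.shape)
        if open_mask and b > 1e-6:
            u0 = float(np.interp(np.mod(phi, 1.0), grid, u0_of_phase, period=1.0))
            c, s = np.cos(angle), np.sin(angle)
            u = x * c + y * s
            v = -x * s + y * c
            e = (u / a) ** 2 + (v / b) ** 2
            inside = e <= 1.0
            vel = u0 * (1.0 - e) * inside          # mm/s, axial profile
            vz = vel * np.cos(theta)
            phase_img = velocity_to_phase(vz, doppler)
        if rng is not None and config.phase_noise_sd_rad > 0:
            phase_img = phase_img + rng.normal(
                0.0, config.phase_noise_sd_rad, size=phase_img.shape)
        out[k] = wrap_phase(phase_img)
    return out


def render_sequences(config: PhantomConfig | None = None, *,
                     include_doppler: bool = True, n_phases: int = 196,
                     flow_cfg=None) -> tuple[list[ImageSequence], GroundTruth]:
    """Render all per-plane image sequences plus the full ground truth.

    Each plane's sequence starts at an independent, uniformly drawn cardiac
    phase (acquisition is untriggered), recorded in the ground truth.  Output
    is bit-reproducible for a fixed ``config.seed``.
    """
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    start_phase = rng.uniform(0.0, 1.0, size=config.n_planes)

    phases = np.arange(n_phases) / n_phases
    delta = config.wave_delay_cycles
    pf = config.period_frames
    observed = np.mod(start_phase - delta, 1.0)
    lag_frames = np.mod(observed[0] - observed, 1.0) * pf

    npl, nph = config.n_planes, n_phases
    tr = dict(r_inner_mm=np.zeros((npl, nph)), r_outer_mm=np.zeros((npl, nph)),
              lumen_area_mm2=np.zeros((npl, nph)), jelly_area_mm2=np.zeros((npl, nph)),
              a_mm=np.zeros((npl, nph)), b_mm=np.zeros((npl, nph)),
              open_mask=np.zeros((npl, nph), dtype=bool))
    angles = np.zeros(npl)
    for i, z in enumerate(config.z_planes_um):
        r_in, r_out, a_lum, a_jel, a, b, ang, opn = _geometry_arrays(config, z, phases)
        tr["r_inner_mm"][i], tr["r_outer_mm"][i] = r_in, r_out
        tr["lumen_area_mm2"][i], tr["jelly_area_mm2"][i] = a_lum, a_jel
        tr["a_mm"][i], tr["b_mm"][i], tr["open_mask"][i] = a, b, opn
        angles[i] = ang

    pv, pa = _pressure_on_phases(config, phases)
    vent, aos = generate_pressure_traces(config)

    truth = GroundTruth(
        config=config, start_phase=start_phase, wave_delay_cycles=delta,
        lag_frames=lag_frames, phases=phases, angle_rad=angles,
        p_vent=vent, p_as=aos, p_vent_phase=pv, p_as_phase=pa, **tr)

    if include_doppler:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flow, u_center = _true_flow(config, truth, flow_cfg)
        truth.flow = flow
        truth.centerline_velocity_mm_s = u_center

    x, y, r, atten = _pixel_grid(config)
    noise_rng = rng if config.speckle_contrast > 0 or config.phase_noise_sd_rad > 0 \
        else None
    sequences = []
    frames_idx = np.arange(config.n_frames)
    for i, z in enumerate(config.z_planes_um):
        fr_phase = truth.frame_phase(i, frames_idx)
        stack = np.empty((config.n_frames, config.image_size_px,
                          config.image_size_px), dtype=np.float32)
        for k, phi in enumerate(fr_phase):
            stack[k] = _render_intensity_frame(config, z, float(phi), x, y, r,
                                               atten, noise_rng)
        phase_stack = None
        if include_doppler:
            phase_stack = render_doppler_phase(
                truth.centerline_velocity_mm_s[i], config, i,
                rng=noise_rng, frame_phases=fr_phase)
        sequences.append(ImageSequence(
            frames=stack, phase=phase_stack,
            pixel_pitch_um=config.pixel_pitch_um,
            frame_rate_hz=config.frame_rate_hz, plane_id=i))
    return sequences, truth
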