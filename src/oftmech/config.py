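"""Configuration objects for the phantom generator and the analysis pipeline.

All geometric defaults describe a Hamburger-Hamilton stage-18 chick heart
outflow tract (OFT): a ~600 um long tapered tube whose wall is a bright
myocardial ring, a dark cardiac-jelly layer forming two spiralling endocardial
cushions, and a lumen whose backscatter level is indistinguishable from the
endocardium.  Units are carried in field names (um, mm, s, Pa, Hz, deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PhantomConfig",
    "DopplerConfig",
    "SegmentationConfig",
    "FlowConfig",
    "RunConfig",
    "load_run_config",
    "save_run_config",
]


def _interp_defaults(values: Sequence[float], n: int) -> tuple[float, ...]:
    """Resample a per-plane default tuple onto ``n`` evenly spaced planes."""
    v = np.asarray(values, dtype=float)
    if n == len(v):
        return tuple(v)
    x_old = np.linspace(0.0, 1.0, len(v))
    x_new = np.linspace(0.0, 1.0, n)
    return tuple(float(x) for x in np.interp(x_new, x_old, v))


@dataclass(frozen=True)
class PhantomConfig:
    """Parametric description of the synthetic OFT phantom.

    The per-plane tuples (radii, wall thickness, Doppler angle) are indexed
    proximal (near the ventricle) to distal (near the aortic sac).  Radii are
    inner myocardial radii; the lumen inside is carved out of the inner circle
    by two diametrically opposed cardiac-jelly lobes whose orientation rotates
    along the tube at ``cushion_spiral_rate_deg_per_um``.
    """

    # geometry
    tube_length_um: float = 600.0
    n_planes: int = 5
    r_inner_max_mm: tuple[float, ...] = (0.21, 0.20, 0.19, 0.17, 0.15)
    r_inner_min_mm: tuple[float, ...] = (0.14, 0.13, 0.12, 0.11, 0.12)
    myo_thickness_mm: tuple[float, ...] = (0.060, 0.052, 0.045, 0.038, 0.028)
    jelly_margin_mm: float = 0.025       # jelly left between lumen tip and myocardium
    jelly_asf: float = 0.4               # fractional cyclic change of jelly area
    cushion_spiral_rate_deg_per_um: float = 0.15
    cushion_angle0_deg: float = 0.0

    # dynamics
    period_s: float = 0.37
    frame_rate_hz: float = 140.0
    n_cycles: int = 4
    peristaltic_wave_speed_um_s: float = 20000.0
    closure_fraction_target: float = 0.5

    # pressures
    p_vent_peak_pa: float = 196.0
    p_as_peak_pa: float = 180.0
    p_vent_dia_pa: float = 20.0
    p_as_dia_pa: float = 60.0
    p_vent_width_cycle: float = 0.60
    p_as_width_cycle: float = 0.45
    pressure_rate_hz: float = 100.0
    pressure_n_cycles: int = 10

    # imaging
    pixel_pitch_um: float = 5.0
    image_size_px: int = 128
    doppler_angle_deg: tuple[float, ...] = (84.0, 58.4, 65.0, 70.0, 75.0)
    intensity_background: float = 0.05
    intensity_myocardium: float = 0.85
    intensity_jelly: float = 0.18
    intensity_lumen: float = 0.50
    speckle_contrast: float = 0.25       # 1/sqrt(k) of the multiplicative gamma noise
    phase_noise_sd_rad: float = 0.12
    attenuation_per_mm: float = 0.4      # exponential decay along the beam (row) axis

    seed: int = 0

    # -- derived quantities ------------------------------------------------
    @property
    def z_planes_um(self) -> np.ndarray:
        return np.linspace(0.0, self.tube_length_um, self.n_planes)

    @property
    def period_frames(self) -> float:
        return self.period_s * self.frame_rate_hz

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.n_cycles * self.period_frames))

    @property
    def wave_delay_cycles(self) -> np.ndarray:
        """Peristaltic phase delay of each plane, as a fraction of the cycle."""
        return self.z_planes_um / (self.peristaltic_wave_speed_um_s * self.period_s)

    @property
    def open_duty(self) -> float:
        """Fraction of the cycle each plane's lumen is open.

        Chosen so that the fraction of the cycle during which *all* planes are
        simultaneously closed equals ``closure_fraction_target``: the per-plane
        open intervals are staggered by the peristaltic delay, so the union of
        open intervals spans ``open_duty + max delay``.
        """
        return 1.0 - self.closure_fraction_target - float(self.wave_delay_cycles[-1])

    def validate(self) -> None:
        per_plane = {
            "r_inner_max_mm": self.r_inner_max_mm,
            "r_inner_min_mm": self.r_inner_min_mm,
            "myo_thickness_mm": self.myo_thickness_mm,
            "doppler_angle_deg": self.doppler_angle_deg,
        }
        for name, vals in per_plane.items():
            if len(vals) != self.n_planes:
                raise ValueError(f"{name} must have {self.n_planes} entries, got {len(vals)}")
        rmax = np.asarray(self.r_inner_max_mm)
        rmin = np.asarray(self.r_inner_min_mm)
        if np.any(np.diff(rmax) > 1e-12):
            raise ValueError("r_inner_max_mm must be non-increasing proximal to distal")
        if np.any(rmin >= rmax):
            raise ValueError("r_inner_min_mm must be < r_inner_max_mm at every plane")
        if np.any(rmin <= 0):
            raise ValueError("radii must be positive")
        for name in ("tube_length_um", "period_s", "frame_rate_hz", "pixel_pitch_um",
                     "peristaltic_wave_speed_um_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cycles < 2:
            raise ValueError("need at least two cardiac cycles for synchronization")
        if not 0.0 < self.open_duty < 1.0:
            raise ValueError(
                "closure_fraction_target plus the peristaltic delay leaves no open window"
            )
        if np.any(np.asarray(self.myo_thickness_mm) <= 0):
            raise ValueError("myocardial thickness must be positive")

    @classmethod
    def with_n_planes(cls, n: int, **overrides) -> "PhantomConfig":
        """A config whose per-plane defaults are resampled onto ``n`` planes."""
        base = cls()
        fields = {}
        for name in ("r_inner_max_mm", "r_inner_min_mm", "myo_thickness_mm",
                     "doppler_angle_deg"):
            fields[name] = _interp_defaults(getattr(base, name), n)
        fields.update(overrides)
        return cls(n_planes=n, **fields)

    def replace(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class DopplerConfig:
    """Spectral-domain OCT Doppler constants.

    ``velocity_limit_mm_s`` is the largest axial velocity measurable before
    the inter-A-scan phase difference wraps past pi.
    """

    wavelength_m: float = 1310e-9
    refractive_index: float = 1.3
    inter_ascan_time_s: float = 21e-6

    def validate(self) -> None:
        if self.wavelength_m <= 0 or self.inter_ascan_time_s <= 0:
            raise ValueError("wavelength and inter-A-scan time must be positive")
        if not 1.0 <= self.refractive_index <= 2.0:
            raise ValueError("refractive index outside plausible tissue range")

    @property
    def velocity_limit_mm_s(self) -> float:
        """Axial velocity mapped to a phase difference of pi, in mm/s."""
        return 1e3 * self.wavelength_m / (4.0 * self.refractive_index * self.inter_ascan_time_s)


@dataclass(frozen=True)
class SegmentationConfig:
    """Active-contour (snake) and layer-threshold parameters."""

    alpha: float = 0.1            # first-derivative (elasticity) weight
    beta: float = 0.05            # second-derivative (stiffness) weight
    gamma: float = 1.0            # implicit Euler step size
    kappa: float = 2.0            # external force weight, px
    sigma_px: float = 2.0         # Gaussian smoothing of the image before gradients
    force_sigma_px: float = 3.0   # diffusion of the edge-force field
    n_vertices: int = 64
    max_iter: int = 200
    tol_px: float = 0.1
    myo_threshold: float = 0.65   # on the attenuation-compensated intensity
    lumen_low: float = 0.34       # midpoint of the jelly and lumen levels
    lumen_high: float = 0.67      # midpoint of the lumen and myocardium levels
    min_lumen_px: int = 20        # below this the lumen is treated as closed (slit)


@dataclass(frozen=True)
class FlowConfig:
    """Reduced-order lumen flow model parameters."""

    mu_pa_s: float = 3.0e-3
    window_cycle: tuple[float, float] = (0.43, 0.93)
    n_steps: int = 200
    n_z: int = 101
    b_floor_mm: float = 1.0e-3
    auto_window: bool = True      # widen/narrow the window to the phases with open lumen
    rho_kg_m3: float = 1060.0     # only used by the optional inertial correction
    inertial_correction: bool = False


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: one seed drives all randomness."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    doppler: DopplerConfig = field(default_factory=DopplerConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    n_phases: int = 196
    seed: int = 0
    outdir: str | None = None
    enable_flow: bool = True
    pressure_alignment: str = "peak_pressure_at_peak_area"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed != self.phantom.seed:
            self.phantom = self.phantom.replace(seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def _dict_to_run_config(d: dict) -> RunConfig:
    def _tupled(cls, block):
        kwargs = dict(block or {})
        for k, v in kwargs.items():
            if isinstance(v, list):
                kwargs[k] = tuple(v)
        return cls(**kwargs)

    return RunConfig(
        phantom=_tupled(PhantomConfig, d.get("phantom")),
        doppler=_tupled(DopplerConfig, d.get("doppler")),
        segmentation=_tupled(SegmentationConfig, d.get("segmentation")),
        flow=_tupled(FlowConfig, d.get("flow")),
        **{k: v for k, v in d.items()
           if k not in ("phantom", "doppler", "segmentation", "flow")},
    )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return _dict_to_run_config(yaml.safe_load(fh) or {})


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
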