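"""Doppler OCT velocimetry: phase-to-velocity conversion, angle correction,
temporal phase unwrapping, and centerline velocity extraction.

The inter-A-scan phase difference of a spectral-domain OCT system measures
the velocity component along the beam,

    V_z = lambda0 * dphi / (4 pi n tau),

with ``lambda0`` the central wavelength, ``n`` the tissue refractive index
and ``tau`` the time between adjacent A-scans.  With the defaults
(1310 nm, n = 1.3, tau = 21 us) a phase of pi maps to ~12 mm/s, the
unambiguous detection limit; temporal unwrapping doubles it, and dividing by
cos(theta) of the Doppler angle converts axial to flow velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import DopplerConfig

__all__ = [
    "phase_to_velocity",
    "velocity_to_phase",
    "angle_correct",
    "unwrap_phase",
    "wrap_phase",
    "centerline_velocity_series",
    "VelocitySeries",
]


def wrap_phase(phi: np.ndarray | float) -> np.ndarray:
    """Wrap phase into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2.0 * np.pi)


def phase_to_velocity(dphi: np.ndarray | float, cfg: DopplerConfig | None = None
                      ) -> np.ndarray | float:
    """Axial (beam-direction) velocity in mm/s from inter-A-scan phase in radians."""
    cfg = cfg or DopplerConfig()
    v = 1e3 * cfg.wavelength_m * np.asarray(dphi, dtype=float) / (
        4.0 * np.pi * cfg.refractive_index * cfg.inter_ascan_time_s)
    return v if np.ndim(dphi) else float(v)


def velocity_to_phase(v_z_mm_s: np.ndarray | float, cfg: DopplerConfig | None = None
                      ) -> np.ndarray | float:
    """Unwrapped inter-A-scan phase in radians from axial velocity in mm/s."""
    cfg = cfg or DopplerConfig()
    p = 4.0 * np.pi * cfg.refractive_index * cfg.inter_ascan_time_s \
        * np.asarray(v_z_mm_s, dtype=float) / (1e3 * cfg.wavelength_m)
    return p if np.ndim(v_z_mm_s) else float(p)


def angle_correct(v_z: np.ndarray | float, theta_deg: float) -> np.ndarray | float:
    """Flow-velocity magnitude from the axial component and the Doppler angle.

    Raises ``ValueError`` at theta = 90 deg, where the beam is perpendicular
    to the flow and carries no Doppler signal.
    """
    c = np.cos(np.deg2rad(theta_deg))
    if abs(c) < 1e-12:
        raise ValueError("Doppler angle of 90 degrees leaves no axial component")
    out = np.asarray(v_z, dtype=float) / c
    return out if np.ndim(v_z) else float(out)


def unwrap_phase(dphi: np.ndarray) -> np.ndarray:
    """1-D temporal unwrapping: remove 2*pi jumps between successive samples."""
    return np.unwrap(np.asarray(dphi, dtype=float))


@dataclass
class VelocitySeries:
    """Centerline velocity over the cycle with closed-lumen/plateau masking."""

    times_s: np.ndarray
    velocity_mm_s: np.ndarray      # angle-corrected magnitude, NaN where masked
    v_axial_mm_s: np.ndarray       # unwrapped axial component
    masked: np.ndarray             # True where the lumen is closed (no sample)
    plateau: np.ndarray            # True where the unwrapped range is saturated
    theta_deg: float

    @property
    def valid(self) -> np.ndarray:
        return ~self.masked & ~self.plateau


def centerline_velocity_series(mphase: np.ndarray, row: int,
                               cfg: DopplerConfig | None = None,
                               theta_deg: float = 0.0,
                               times_s: np.ndarray | None = None,
                               open_mask: np.ndarray | None = None,
                               avg_halfwidth: int = 2,
                               plateau_fraction: float = 0.95) -> VelocitySeries:
    """Velocity over time at one spatial sample of an M-phase raster.

    ``mphase`` is (space, time) wrapped phase.  The phase at ``row`` (averaged
    as a complex phasor over ``2*avg_halfwidth + 1`` neighbouring rows to
    suppress phase noise) is unwrapped over time and converted through the
    Doppler equations.  Frames with a closed lumen (``open_mask`` False) are
    reported as missing, not zero.  Samples whose unwrapped axial velocity
    saturates near twice the single-pass limit are flagged as a wrap-plateau
    artifact: the true velocity there exceeds what unwrapping can recover.
    """
    cfg = cfg or DopplerConfig()
    mphase = np.asarray(mphase, dtype=float)
    nspace, nt = mphase.shape
    if not 0 <= row < nspace:
        raise ValueError("row outside the M-phase raster")
    lo = max(0, row - avg_halfwidth)
    hi = min(nspace, row + avg_halfwidth + 1)
    phasor = np.exp(1j * mphase[lo:hi]).mean(axis=0)
    phi = np.angle(phasor)

    if open_mask is None:
        open_mask = np.ones(nt, dtype=bool)
    open_mask = np.asarray(open_mask, dtype=bool)
    masked = ~open_mask

    # unwrap only over the open samples of each contiguous open stretch
    phi_unwrapped = phi.copy()
    idx = np.flatnonzero(open_mask)
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for seg in np.split(idx, splits):
            phi_unwrapped[seg] = np.unwrap(phi[seg])

    v_axial = phase_to_velocity(phi_unwrapped, cfg)
    # one temporal unwrap doubles the unambiguous range; beyond it the
    # measurement saturates into the characteristic plateau artifact
    limit2 = 2.0 * cfg.velocity_limit_mm_s
    plateau = open_mask & (np.abs(v_axial) >= plateau_fraction * limit2)
    v_axial = np.clip(v_axial, -limit2, limit2)
    if np.any(plateau):
        warnings.warn("velocity saturates the unwrapped detection range; "
                      "plateau samples flagged", stacklevel=2)
    velocity = angle_correct(v_axial, theta_deg)
    velocity = np.where(open_mask, velocity, np.nan)
    v_axial = np.where(open_mask, v_axial, np.nan)
    if times_s is None:
        times_s = np.arange(nt, dtype=float)
    return VelocitySeries(times_s=np.asarray(times_s, dtype=float),
                          velocity_mm_s=velocity, v_axial_mm_s=v_axial,
                          masked=masked, plateau=plateau, theta_deg=theta_deg)
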