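"""Laplace-law circumferential wall stress along the outflow tract.

The myocardium is approximated as a thin-walled cylinder:
``sigma_theta = P * R / h`` with ``P`` the intracardiac pressure, ``R`` the
inner myocardial radius and ``h`` the average wall thickness.  Pressure at a
plane a fraction ``s`` of the way from the ventricle to the aortic sac is a
linear blend of the two measured traces.  Because pressures and wall motion
come from different embryos, their phase relationship is set by an explicit
rule — by default, peak ventricular pressure is aligned with peak lumen area
at the proximal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PressureTrace",
    "fold_pressure",
    "align_pressure_phase",
    "interpolate_pressure",
    "laplace_stress",
    "stress_profile",
]


@dataclass
class PressureTrace:
    """Uniformly sampled blood-pressure trace from one measurement site."""

    time_s: np.ndarray
    pressure_pa: np.ndarray
    site: str = "ventricle"
    sampling_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_pa = np.asarray(self.pressure_pa, dtype=float)
        if self.time_s.shape != self.pressure_pa.shape:
            raise ValueError("time and pressure must have equal length")

    @property
    def peak_pa(self) -> float:
        return float(self.pressure_pa.max())

    def estimate_period_s(self) -> float:
        from .reconstruction import estimate_period
        frames = estimate_period(self.pressure_pa - self.pressure_pa.mean())
        return frames / self.sampling_rate_hz


def fold_pressure(trace: PressureTrace, period_s: float, n_phases: int
                  ) -> np.ndarray:
    """Fold a multi-cycle trace onto one cycle of ``n_phases`` bins (bin means)."""
    if trace.time_s[-1] - trace.time_s[0] < period_s:
        raise ValueError("trace shorter than one period")
    phases = np.mod(trace.time_s / period_s, 1.0)
    bins = np.minimum((phases * n_phases).astype(int), n_phases - 1)
    acc = np.bincount(bins, weights=trace.pressure_pa, minlength=n_phases)
    cnt = np.bincount(bins, minlength=n_phases).astype(float)
    out = np.full(n_phases, np.nan)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz]
    if not nz.all():
        grid = np.arange(n_phases)
        out = np.interp(grid, grid[nz], out[nz], period=n_phases)
    return out


def align_pressure_phase(trace: PressureTrace, lumen_area: np.ndarray,
                         period_s: float | None = None,
                         rule: str = "peak_pressure_at_peak_area"):
    """Fold a trace to the kinematics phase grid and phase-align it.

    ``lumen_area`` is the proximal-plane lumen area on the canonical phase
    grid.  Returns ``(aligned pressure on the grid, shift in phase bins)``.
    Raises if the trace shows no periodic structure.
    """
    n_phases = np.asarray(lumen_area).size
    if period_s is None:
        period_s = trace.estimate_period_s()
    folded = fold_pressure(trace, period_s, n_phases)
    if rule == "none":
        return folded, 0
    if rule != "peak_pressure_at_peak_area":
        raise ValueError(f"unknown alignment rule {rule!r}")
    shift = int(np.argmax(lumen_area)) - int(np.argmax(folded))
    return np.roll(folded, shift), shift


def interpolate_pressure(p_vent: np.ndarray, p_as: np.ndarray,
                         s: float) -> np.ndarray:
    """Pressure at normalized position ``s`` (0 = ventricle end, 1 = aortic sac)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("normalized position must lie in [0, 1]")
    return (1.0 - s) * np.asarray(p_vent, float) + s * np.asarray(p_as, float)


def laplace_stress(p_pa, r_mm, h_mm):
    """Thin-wall circumferential stress ``sigma = P R / h`` in Pa."""
    h = np.asarray(h_mm, dtype=float)
    if np.any(h <= 0):
        raise ValueError("wall thickness must be positive")
    out = np.asarray(p_pa, dtype=float) * np.asarray(r_mm, dtype=float) / h
    return out if np.ndim(out) else float(out)


def stress_profile(kin: pd.DataFrame, p_vent: np.ndarray, p_as: np.ndarray,
                   h_mm_by_plane: dict[int, float] | None = None) -> pd.DataFrame:
    """Per-plane, per-phase wall stress from aligned pressures and kinematics.

    ``kin`` is the tidy kinematics table (needs ``R_eff_mm`` and, unless
    ``h_mm_by_plane`` overrides it, the contour-derived ``h_myo_mm``).  Wall
    thickness enters as its cycle average per plane.  Planes are placed at
    equal normalized positions between the ventricle and the aortic sac.
    """
    planes = sorted(kin["plane"].unique())
    if len(planes) < 2:
        raise ValueError("need at least two planes")
    rows = []
    for j, plane in enumerate(planes):
        g = kin[kin["plane"] == plane].sort_values("phase_index")
        s = j / (len(planes) - 1)
        p = interpolate_pressure(p_vent, p_as, s)
        if h_mm_by_plane is not None:
            h = h_mm_by_plane[plane]
        else:
            h = float(g["h_myo_mm"].mean())
        if not np.isfinite(h) or h <= 0:
            raise ValueError(f"missing wall thickness for plane {plane}")
        r = g["R_eff_mm"].to_numpy()
        rows.append(pd.DataFrame({
            "plane": plane, "phase": g["phase"].to_numpy(),
            "position_s": s, "P_pa": p, "R_mm": r, "h_mm": h,
            "sigma_pa": laplace_stress(p, r, h),
        }))
    return pd.concat(rows, ignore_index=True)
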