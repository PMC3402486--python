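"""Wall-motion metrics of the outflow tract from contour series.

Conventions
-----------
* Circumferential strain is referenced to the *largest* perimeter over the
  cycle and is positive in contraction: ``eps(t) = (C_max - C(t)) / C_max``.
* The myocardium is treated as circular through its effective radius
  ``R_eff = sqrt(A_inner / pi)``, so myocardial strain equals
  ``(R_max - R(t)) / R_max``.
* Area shortening fraction: ``ASF = (A_max - A_min) / A_max``.
* Cardiac-jelly area is the inner-myocardial area minus the lumen area.
* Timing fractions split the cycle into expanding (dA/dt > 0), contracting
  (dA/dt < 0) and closed (area within a small tolerance of its minimum).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .segmentation import Contour, ContourSeries

__all__ = [
    "circumferential_strain",
    "area_shortening_fraction",
    "radial_velocity",
    "shape_factor",
    "phase_timings",
    "endocardial_thickness",
    "longitudinal_stretch",
    "build_kinematics",
    "summary_table",
]


def circumferential_strain(perimeters: np.ndarray) -> np.ndarray:
    """Contraction-positive circumferential strain series from a perimeter series."""
    c = np.asarray(perimeters, dtype=float)
    if c.size == 0:
        raise ValueError("empty perimeter series")
    if np.any(c <= 0):
        raise ValueError("perimeters must be positive")
    cmax = c.max()
    return (cmax - c) / cmax


def area_shortening_fraction(areas: np.ndarray) -> float:
    """(A_max - A_min) / A_max over the cycle."""
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise ValueError("empty area series")
    if np.any(a < 0):
        raise ValueError("areas must be non-negative")
    amax = a.max()
    if amax == 0:
        raise ValueError("ASF undefined for an identically zero area series")
    return float((amax - a.min()) / amax)


def _periodic_gradient(y: np.ndarray, dt: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples for a periodic derivative")
    return (np.roll(y, -1) - np.roll(y, 1)) / (2.0 * dt)


def radial_velocity(radius: np.ndarray, dt_s: float):
    """Centered-difference dR/dt on the periodic phase grid.

    Returns ``(dRdt, max_expansion, max_contraction)`` with both extrema
    reported as positive speeds (mm/s).
    """
    drdt = _periodic_gradient(radius, dt_s)
    return drdt, float(drdt.max()), float(-drdt.min())


def shape_factor(contour: Contour | np.ndarray) -> float:
    """Major/minor axis ratio of the least-squares fitted ellipse (>= 1)."""
    from .hemodynamics import fit_ellipse

    pts = contour.vertices_px if isinstance(contour, Contour) else np.asarray(contour)
    if pts.shape[0] < 5:
        raise ValueError("need >= 5 points for an ellipse fit")
    spread = pts.std(axis=0)
    if np.any(spread < 1e-9):
        raise ValueError("degenerate contour: zero extent")
    _, _, a, b, _ = fit_ellipse(pts.astype(float))
    return float(a / b)


def phase_timings(areas: np.ndarray, closure_tol: float = 0.05):
    """Fractions of the cycle spent expanding, contracting and closed.

    A phase is *closed* when the area lies within ``closure_tol`` of the
    cyclic dynamic range above the minimum; the remaining (open) phases are
    split by the sign of the centered periodic derivative.  A flat series is
    reported as fully closed with a warning.
    """
    a = np.asarray(areas, dtype=float)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 phases")
    rng = a.max() - a.min()
    if rng == 0:
        warnings.warn("flat area series: reporting the full cycle as closed",
                      stacklevel=2)
        return 0.0, 0.0, 1.0
    closed = a <= a.min() + closure_tol * rng
    dadt = _periodic_gradient(a, 1.0 / n)
    expanding = ~closed & (dadt > 0)
    contracting = ~closed & ~expanding
    return (float(expanding.mean()), float(contracting.mean()),
            float(closed.mean()))


def endocardial_thickness(c_min_mm: float, a_min_mm2: float,
                          model: str = "slit") -> float:
    """Endocardial layer thickness in um from the closed-lumen boundary.

    ``slit``: the boundary wraps a flat ribbon of length ~C/2, so
    ``t = 2 A / C``; ``annulus``: the area is a thin band along the full
    boundary, ``t = A / C``.
    """
    if c_min_mm <= 0:
        raise ValueError("perimeter must be positive")
    if model == "slit":
        t_mm = 2.0 * a_min_mm2 / c_min_mm
    elif model == "annulus":
        t_mm = a_min_mm2 / c_min_mm
    else:
        raise ValueError(f"unknown thickness model {model!r}")
    return 1e3 * t_mm


def longitudinal_stretch(displacement_um: float, length_um: float) -> float:
    """Longitudinal strain of the tract from a tracked landmark displacement."""
    if length_um <= 0:
        raise ValueError("length must be positive")
    return displacement_um / length_um


# ---------------------------------------------------------------------------
# tables


def build_kinematics(series_by_plane: dict[int, ContourSeries], period_s: float,
                     closure_tol: float = 0.05) -> pd.DataFrame:
    """Tidy per-plane, per-phase kinematics table from contour series.

    Expects one ``ContourSeries`` per plane with ``myo_outer``, ``myo_inner``
    and ``endo`` contours at every phase of one canonical cycle.
    """
    rows = []
    for plane, series in sorted(series_by_plane.items()):
        a_inner = series.areas_mm2("myo_inner")
        a_outer = series.areas_mm2("myo_outer")
        a_lumen = series.areas_mm2("endo")
        c_endo = series.perimeters_mm("endo")
        n = a_inner.size
        dt = period_s / n
        r_eff = np.sqrt(a_inner / np.pi)
        r_out_eff = np.sqrt(a_outer / np.pi)
        a_jelly = a_inner - a_lumen
        c_myo = 2.0 * np.pi * r_eff
        eps_myo = circumferential_strain(c_myo)
        eps_endo = circumferential_strain(c_endo)
        drdt = _periodic_gradient(r_eff, dt)
        depsdt = _periodic_gradient(eps_myo, dt)
        lam = np.full(n, np.nan)
        for t, c in enumerate(series.contours["endo"]):
            if not c.degenerate:
                try:
                    lam[t] = shape_factor(c)
                except ValueError:
                    pass
        rows.append(pd.DataFrame({
            "plane": plane, "phase_index": np.arange(n),
            "phase": np.arange(n) / n,
            "C_endo_mm": c_endo, "A_lumen_mm2": a_lumen,
            "A_myo_inner_mm2": a_inner, "A_myo_outer_mm2": a_outer,
            "A_jelly_mm2": a_jelly, "R_eff_mm": r_eff,
            "h_myo_mm": r_out_eff - r_eff,
            "lambda": lam, "eps_theta_myo": eps_myo, "eps_theta_endo": eps_endo,
            "dRdt_mm_s": drdt, "depsdt_1_s": depsdt,
        }))
    return pd.concat(rows, ignore_index=True)


def summary_table(kin: pd.DataFrame, closure_tol: float = 0.05) -> pd.DataFrame:
    """Per-plane cycle summaries in the layout of the wall-motion table:
    myocardium, cardiac jelly, endocardium and lumen blocks."""
    out = []
    for plane, g in kin.groupby("plane"):
        lam = g["lambda"].dropna()
        te, tc, tcl = phase_timings(g["A_lumen_mm2"].to_numpy(), closure_tol)
        row = {
            "plane": plane,
            "myo_R_max_mm": g["R_eff_mm"].max(),
            "myo_R_min_mm": g["R_eff_mm"].min(),
            "myo_dR_mm": g["R_eff_mm"].max() - g["R_eff_mm"].min(),
            "myo_peak_eps_theta": g["eps_theta_myo"].max(),
            "myo_h_mean_mm": g["h_myo_mm"].mean(),
            "jelly_A_max_mm2": g["A_jelly_mm2"].max(),
            "jelly_A_min_mm2": g["A_jelly_mm2"].min(),
            "jelly_dA_mm2": g["A_jelly_mm2"].max() - g["A_jelly_mm2"].min(),
            "jelly_ASF": area_shortening_fraction(
                np.maximum(g["A_jelly_mm2"].to_numpy(), 0.0)),
            "endo_C_max_mm": g["C_endo_mm"].max(),
            "endo_C_min_mm": g["C_endo_mm"].min(),
            "endo_peak_eps_theta": g["eps_theta_endo"].max(),
            "lumen_A_max_mm2": g["A_lumen_mm2"].max(),
            "lumen_A_min_mm2": g["A_lumen_mm2"].min(),
            "lumen_dA_mm2": g["A_lumen_mm2"].max() - g["A_lumen_mm2"].min(),
            "lumen_ASF": area_shortening_fraction(g["A_lumen_mm2"].to_numpy()),
            "lumen_lambda_max": lam.max() if lam.size else np.nan,
            "lumen_lambda_min": lam.min() if lam.size else np.nan,
            "T_e_frac": te, "T_c_frac": tc, "T_closure_frac": tcl,
            "dRdt_max_expansion_mm_s": g["dRdt_mm_s"].max(),
            "dRdt_max_contraction_mm_s": -g["dRdt_mm_s"].min(),
        }
        out.append(row)
    return pd.DataFrame(out)
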