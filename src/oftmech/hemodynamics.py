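"""Reduced-order pulsatile flow and wall shear stress in the moving lumen.

The lumen is a tapered duct of elliptical cross-section whose semi-axes
``a(z, t) >= b(z, t)`` are fitted from segmentations at the analysis planes
and interpolated along the tract.  At the Reynolds numbers of the early
embryonic outflow tract (order 1-10) inertia is a small correction, so each
instant is solved as a quasi-steady elliptical Poiseuille flow with moving
walls:

* mass conservation with wall motion,  dA/dt + dQ/dz = 0, fixes the axial
  profile of the volumetric flow ``Q(z, t)`` up to the inlet value;
* the measured ventricle-to-aortic-sac pressure drop closes the problem
  through the elliptical-duct resistance density
  ``R_hyd = 4 mu (a^2 + b^2) / (pi a^3 b^3)``:

      dP(t) = integral_0^L R_hyd(z, t) Q(z, t) dz.

Centerline velocity follows from the parabolic profile, ``U0 = 2 Q/(pi a b)``,
and wall shear stress from its wall-normal gradient,
``tau(s) = 2 mu |U0| sqrt(cos^2 s / a^2 + sin^2 s / b^2)`` at the ellipse
point ``(a cos s, b sin s)`` — maximal at the minor-axis ends, i.e. on the
cushion surfaces.  Units: mm, s, Pa, mm^3/s; viscosity in Pa s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, simpson
from scipy.interpolate import PchipInterpolator

from .segmentation import Contour, ContourSeries

__all__ = [
    "fit_ellipse",
    "LumenModel",
    "FlowSolution",
    "fit_ellipse_series",
    "build_lumen_model",
    "solve_flow",
    "wss_field",
    "summarize",
    "compare_with_doppler",
]


def fit_ellipse(pts: np.ndarray) -> tuple[float, float, float, float, float]:
    """Least-squares ellipse fit: returns (xc, yc, a, b, theta) with a >= b.

    Wraps the scikit-image estimator across its old and new interfaces.
    """
    from skimage.measure import EllipseModel

    pts = np.asarray(pts, dtype=float)
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("ellipse fit failed")
        xc, yc = model.center
        a, b = model.axis_lengths
        th = model.theta
    else:  # pragma: no cover - older scikit-image
        model = EllipseModel()
        if not model.estimate(pts):
            raise ValueError("ellipse fit failed")
        xc, yc, a, b, th = model.params
    if b > a:
        a, b = b, a
        th = th + np.pi / 2.0
    if min(a, b) <= 0:
        raise ValueError("degenerate ellipse fit")
    return float(xc), float(yc), float(a), float(b), float(np.mod(th, np.pi))


# ---------------------------------------------------------------------------
# lumen model


@dataclass
class LumenModel:
    """Elliptical lumen axes at the analysis stations over one cycle."""

    z_mm: np.ndarray          # (n_stations,) axial positions
    phases: np.ndarray        # (n_phases,) cycle fractions
    a_mm: np.ndarray          # (n_stations, n_phases) semi-major axes
    b_mm: np.ndarray          # (n_stations, n_phases) semi-minor (0 = closed)
    angle_rad: np.ndarray     # (n_stations,) major-axis orientation
    period_s: float = 0.37
    mu_pa_s: float = 3.0e-3
    window_cycle: tuple[float, float] = (0.43, 0.93)
    b_floor_mm: float = 1.0e-3

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.a_mm = np.asarray(self.a_mm, dtype=float)
        self.b_mm = np.asarray(self.b_mm, dtype=float)
        if self.a_mm.shape != self.b_mm.shape:
            raise ValueError("a and b must have the same shape")
        if self.a_mm.shape[0] != self.z_mm.size:
            raise ValueError("one row of axes per station required")
        if np.any(self.b_mm - self.a_mm > 1e-9):
            raise ValueError("semi-minor axis exceeds semi-major axis")

    @property
    def length_mm(self) -> float:
        return float(self.z_mm[-1] - self.z_mm[0])

    def open_phases(self, mode: str = "all") -> np.ndarray:
        """Phases at which the lumen is open at every station (``all``) or at
        least one station (``any``)."""
        agg = np.all if mode == "all" else np.any
        return agg(self.b_mm > self.b_floor_mm, axis=0)

    def with_auto_window(self, margin: float = 0.0, min_gap: int = 3,
                         mode: str = "any") -> "LumenModel":
        """Restrict the simulated window to the dominant open phase arc.

        With ``mode='any'`` (default) the window covers every phase at which
        some part of the tract is open, so the peristaltic filling and
        ejection flows at the window edges are continuous; ``mode='all'``
        restricts to the fully open arc.

        Isolated closed phases shorter than ``min_gap`` (single-frame
        segmentation dropouts) are bridged; the longest contiguous circular
        run of open phases then defines the window, shrunk by ``margin``
        (cycle fraction) on each side.
        """
        open_mask = self.open_phases(mode).copy()
        n = open_mask.size
        if not np.any(open_mask):
            raise ValueError("lumen never fully open; no flow window")
        if open_mask.all():
            return replace(self, window_cycle=(0.0 + margin, 1.0 - margin))
        # bridge short closed gaps (circularly)
        idx = np.arange(n)
        closed_runs = []
        prev = open_mask[(idx - 1) % n]
        starts = idx[~open_mask & prev]
        for s in starts:
            e = s
            while not open_mask[e % n]:
                e += 1
            if e - s < min_gap:
                closed_runs.append((s, e))
        for s, e in closed_runs:
            open_mask[np.arange(s, e) % n] = True
        # longest circular open run
        ext = np.concatenate([open_mask, open_mask])
        best_len = best_start = cur = 0
        for i in range(2 * n):
            if ext[i]:
                cur += 1
                if cur > best_len:
                    best_len, best_start = cur, i - cur + 1
            else:
                cur = 0
        best_len = min(best_len, n)
        lo = best_start / n + margin
        hi = (best_start + best_len - 1) / n - margin
        return replace(self, window_cycle=(float(lo), float(hi)))

    def _interp_phase(self, values: np.ndarray, phase: float) -> np.ndarray:
        """Circular linear interpolation along the phase axis at each station."""
        return np.array([
            np.interp(np.mod(phase, 1.0), self.phases, row, period=1.0)
            for row in values])

    def axes_at(self, z: np.ndarray, phase: float) -> tuple[np.ndarray, np.ndarray]:
        """Shape-preserving interpolation of the semi-axes along z at one phase."""
        a_st = self._interp_phase(self.a_mm, phase)
        b_st = self._interp_phase(self.b_mm, phase)
        if self.z_mm.size >= 3:
            a = PchipInterpolator(self.z_mm, a_st)(z)
            b = PchipInterpolator(self.z_mm, b_st)(z)
        else:
            a = np.interp(z, self.z_mm, a_st)
            b = np.interp(z, self.z_mm, b_st)
        return np.maximum(a, 0.0), np.maximum(b, 0.0)

    def area_at(self, z: np.ndarray, phase: float) -> np.ndarray:
        a, b = self.axes_at(z, phase)
        return np.pi * a * b

    def dadt_at(self, z: np.ndarray, phase: float) -> np.ndarray:
        """dA/dt (mm^2/s) by centered differences on the phase grid."""
        h = 1.0 / self.phases.size
        ap = self.area_at(z, phase + h)
        am = self.area_at(z, phase - h)
        return (ap - am) / (2.0 * h * self.period_s)


def fit_ellipse_series(series: ContourSeries, label: str = "endo",
                       b_floor_mm: float = 1e-3) -> pd.DataFrame:
    """Least-squares ellipse per contour: semi-axes, center, orientation and
    the relative area mismatch between the fit and the polygon.

    Degenerate (closed-lumen slit) contours get ``b = b_floor`` and a
    ``closed`` flag instead of a fit.
    """
    rows = []
    pitch_mm = series.pixel_pitch_um * 1e-3
    for c in series.contours[label]:
        rec = dict(plane=series.plane_id, frame=c.frame, closed=False,
                   area_error=np.nan)
        if c.degenerate:
            v = c.vertices_mm
            center = v.mean(axis=0)
            half = np.linalg.norm(v - center, axis=1).max()
            rec.update(a_mm=max(half, b_floor_mm), b_mm=b_floor_mm,
                       xc_mm=center[0], yc_mm=center[1],
                       angle_rad=0.0, closed=True)
        else:
            try:
                xc, yc, a, b, th = fit_ellipse(c.vertices_px)
            except ValueError as err:
                raise ValueError(f"ellipse fit failed at frame {c.frame}") from err
            a_mm, b_mm = a * pitch_mm, b * pitch_mm
            area_fit = np.pi * a_mm * b_mm
            rec.update(a_mm=a_mm, b_mm=max(b_mm, b_floor_mm),
                       xc_mm=xc * pitch_mm, yc_mm=yc * pitch_mm,
                       angle_rad=th,
                       area_error=abs(area_fit - c.area_mm2) / max(c.area_mm2, 1e-12))
        rows.append(rec)
    return pd.DataFrame(rows)


def _circular_mean_angle(angles: np.ndarray) -> float:
    """Mean of axial (mod-pi) orientations via the doubled-angle trick."""
    return float(np.mod(np.angle(np.mean(np.exp(2j * angles))) / 2.0, np.pi))


def build_lumen_model(series_by_plane: dict[int, ContourSeries],
                      z_planes_mm: np.ndarray, period_s: float,
                      mu_pa_s: float = 3.0e-3,
                      window_cycle: tuple[float, float] = (0.43, 0.93),
                      b_floor_mm: float = 1e-3) -> LumenModel:
    """Assemble a :class:`LumenModel` from fitted lumen ellipses per plane."""
    planes = sorted(series_by_plane)
    fits = [fit_ellipse_series(series_by_plane[p], b_floor_mm=b_floor_mm)
            for p in planes]
    n_phases = len(fits[0])
    a = np.vstack([f["a_mm"].to_numpy() for f in fits])
    b = np.vstack([np.where(f["closed"], 0.0, f["b_mm"]) for f in fits])
    ang = np.array([_circular_mean_angle(
        f.loc[~f["closed"], "angle_rad"].to_numpy()) for f in fits])
    return LumenModel(z_mm=np.asarray(z_planes_mm, float),
                      phases=np.arange(n_phases) / n_phases,
                      a_mm=a, b_mm=np.minimum(b, a), angle_rad=ang,
                      period_s=period_s, mu_pa_s=mu_pa_s,
                      window_cycle=window_cycle, b_floor_mm=b_floor_mm)


# ---------------------------------------------------------------------------
# flow solve


@dataclass
class FlowSolution:
    """Quasi-steady flow through the moving duct over the simulated window."""

    t_s: np.ndarray           # (n_t,)
    z_mm: np.ndarray          # (n_z,)
    Q_mm3_s: np.ndarray       # (n_t, n_z)
    Q0_mm3_s: np.ndarray      # inlet flow (n_t,)
    U0_mm_s: np.ndarray       # centerline velocity (n_t, n_z)
    a_mm: np.ndarray          # (n_t, n_z)
    b_mm: np.ndarray
    dAdt_mm2_s: np.ndarray
    dp_pa: np.ndarray         # (n_t,)
    closed: np.ndarray        # (n_t,) any-station closure flag
    period_s: float
    mu_pa_s: float

    @property
    def phases(self) -> np.ndarray:
        return np.mod(self.t_s / self.period_s, 1.0)

    def centerline_velocity_at(self, z: float) -> np.ndarray:
        out = np.empty(self.t_s.size)
        for i in range(self.t_s.size):
            out[i] = np.interp(z, self.z_mm, self.U0_mm_s[i])
        return out

    def mass_residual(self) -> float:
        """max_t of |dA/dt + dQ/dz| integrated over z, relative to peak |Q|.

        dQ/dz uses a fourth-order central stencil in the interior so the
        check resolves the solver's own consistency rather than the
        differentiation error of the check itself.
        """
        qpeak = np.max(np.abs(self.Q_mm3_s))
        if qpeak == 0:
            return 0.0
        dz = self.z_mm[1] - self.z_mm[0]
        worst = 0.0
        for i in range(self.t_s.size):
            if self.closed[i]:
                continue
            q = self.Q_mm3_s[i]
            dqdz = np.gradient(q, self.z_mm)
            dqdz[2:-2] = (q[:-4] - 8 * q[1:-3] + 8 * q[3:-1] - q[4:]) / (12 * dz)
            res = simpson(np.abs(self.dAdt_mm2_s[i] + dqdz), x=self.z_mm)
            worst = max(worst, res / (qpeak * (self.z_mm[-1] - self.z_mm[0])))
        return float(worst)


def _resistance_density(a: np.ndarray, b: np.ndarray, mu: float) -> np.ndarray:
    return 4.0 * mu * (a**2 + b**2) / (np.pi * a**3 * b**3)


def solve_flow(model: LumenModel, dp_phase: np.ndarray, n_steps: int = 200,
               n_z: int = 101) -> FlowSolution:
    """Solve the mass-conserving quasi-steady flow over the model window.

    ``dp_phase`` is the inlet-minus-outlet pressure difference (Pa) on the
    model's phase grid.  The window is discretized into ``n_steps`` uniform
    time steps and the tract into ``n_z`` axial nodes (composite Simpson
    quadrature).  At time steps where any station is closed the through-flow
    is forced to zero downstream of the first closure and the wall-motion
    squeeze flow exits through the inlet.
    """
    if n_z < 51:
        n_z = 51
    if n_z % 2 == 0:
        n_z += 1
    dp_phase = np.asarray(dp_phase, dtype=float)
    if dp_phase.size != model.phases.size:
        raise ValueError("dp must be sampled on the model phase grid")
    lo, hi = model.window_cycle
    t = np.linspace(lo * model.period_s, hi * model.period_s, n_steps + 1)
    z = np.linspace(model.z_mm[0], model.z_mm[-1], n_z)
    nt = t.size
    Q = np.zeros((nt, n_z))
    U0 = np.zeros((nt, n_z))
    A_ = np.zeros((nt, n_z))
    aa = np.zeros((nt, n_z))
    bb = np.zeros((nt, n_z))
    dAdt = np.zeros((nt, n_z))
    Q0 = np.zeros(nt)
    dp_t = np.zeros(nt)
    closed = np.zeros(nt, dtype=bool)
    warned = False
    for i, ti in enumerate(t):
        phase = ti / model.period_s
        a, b = model.axes_at(z, phase)
        aa[i], bb[i] = a, b
        A_[i] = np.pi * a * b
        dAdt[i] = model.dadt_at(z, phase)
        dp_t[i] = np.interp(np.mod(phase, 1.0), model.phases, dp_phase,
                            period=1.0)
        S = cumulative_simpson(dAdt[i], x=z, initial=0.0)
        closed_nodes = b <= model.b_floor_mm
        if np.any(closed_nodes):
            closed[i] = True
            if not warned:
                warnings.warn("lumen closed inside the simulated window; "
                              "flow anchored to zero at the closure front",
                              stacklevel=2)
                warned = True
            # through-flow is blocked: each open segment carries only the
            # wall-motion (squeeze/filling) flow, anchored to Q = 0 at the
            # closure front so the flux exits through the nearer tube end
            Qi = np.zeros(n_z)
            open_nodes_i = ~closed_nodes
            j = 0
            while j < n_z:
                if not open_nodes_i[j]:
                    j += 1
                    continue
                j0 = j
                while j < n_z and open_nodes_i[j]:
                    j += 1
                j1 = j - 1
                seg = slice(j0, j1 + 1)
                if j0 > 0:       # closed proximal neighbour: ejection distally
                    Qi[seg] = -(S[seg] - S[j0])
                else:            # closed distal neighbour: filling from inlet
                    Qi[seg] = S[j1] - S[seg]
        else:
            rhyd = _resistance_density(a, b, model.mu_pa_s)
            if not np.all(np.isfinite(rhyd)):
                raise FloatingPointError("non-finite duct resistance")
            denom = simpson(rhyd, x=z)
            Q0[i] = (dp_t[i] + simpson(rhyd * S, x=z)) / denom
            Qi = Q0[i] - S
        Q[i] = Qi
        open_nodes = A_[i] > np.pi * model.b_floor_mm**2
        U0[i][open_nodes] = 2.0 * Qi[open_nodes] / A_[i][open_nodes]
    return FlowSolution(t_s=t, z_mm=z, Q_mm3_s=Q, Q0_mm3_s=Q0, U0_mm_s=U0,
                        a_mm=aa, b_mm=bb, dAdt_mm2_s=dAdt, dp_pa=dp_t,
                        closed=closed, period_s=model.period_s,
                        mu_pa_s=model.mu_pa_s)


# ---------------------------------------------------------------------------
# wall shear stress


def wss_field(solution: FlowSolution, model: LumenModel, n_s: int = 64):
    """Wall shear stress tau(t, z, s) on the ellipse parameter grid ``s``.

    Closed instants are masked with NaN.  tau is largest at s = +-pi/2, the
    minor-axis ends where the cushion surfaces face each other.
    """
    s = np.linspace(0.0, 2.0 * np.pi, n_s, endpoint=False)
    cs2 = np.cos(s)**2
    sn2 = np.sin(s)**2
    nt, nz = solution.U0_mm_s.shape
    tau = np.full((nt, nz, n_s), np.nan)
    for i in range(nt):
        a, b = solution.a_mm[i], solution.b_mm[i]
        open_nodes = b > model.b_floor_mm
        grad = np.sqrt(cs2[None, :] / np.maximum(a[:, None], 1e-12)**2
                       + sn2[None, :] / np.maximum(b[:, None], 1e-12)**2)
        ti = 2.0 * model.mu_pa_s * np.abs(solution.U0_mm_s[i])[:, None] * grad
        tau[i][open_nodes] = ti[open_nodes]
    return tau, s


def summarize(solution: FlowSolution, model: LumenModel, n_s: int = 64) -> dict:
    """Peak velocity/WSS locations and the unrolled (z, s) WSS map.

    The WSS map is evaluated at the time of peak centerline velocity; the
    ridge of maximal WSS is converted to a laboratory orientation per axial
    node, whose linear trend along z recovers the cushion spiral rate.
    """
    tau, s = wss_field(solution, model, n_s)
    # evaluate the map at peak flow over the fully open steps, where the
    # whole tract contributes
    fully_open = ~solution.closed
    if not np.any(fully_open):
        fully_open = np.ones_like(solution.closed)
    u_masked = np.where(fully_open[:, None], np.abs(solution.U0_mm_s), -np.inf)
    i_u, j_u = np.unravel_index(np.argmax(u_masked), u_masked.shape)
    flat = np.where(np.isnan(tau), -np.inf, tau)
    i_t, j_t, k_t = np.unravel_index(np.argmax(flat), tau.shape)
    wss_map = tau[i_u]  # (z, s) at peak-flow time

    # laboratory orientation of the WSS ridge along z
    if model.z_mm.size >= 3:
        ang_interp = PchipInterpolator(model.z_mm, np.unwrap(2 * model.angle_rad) / 2)
        ang_z = ang_interp(solution.z_mm)
    else:
        ang_z = np.interp(solution.z_mm, model.z_mm,
                          np.unwrap(2 * model.angle_rad) / 2)
    ridge_lab = np.full(solution.z_mm.size, np.nan)
    for j in range(solution.z_mm.size):
        if np.all(np.isnan(wss_map[j])):
            continue
        # the ridge orientation is undefined on near-circular sections
        if solution.a_mm[i_u, j] < 1.02 * solution.b_mm[i_u, j]:
            continue
        k = int(np.nanargmax(wss_map[j]))
        local = np.arctan2(solution.b_mm[i_u, j] * np.sin(s[k]),
                           solution.a_mm[i_u, j] * np.cos(s[k]))
        ridge_lab[j] = ang_z[j] + local
    valid = np.isfinite(ridge_lab)
    spiral_rate = np.nan
    if valid.sum() >= 2:
        # fold the +-pi ambiguity of the slit direction before fitting
        folded = np.unwrap(2 * ridge_lab[valid]) / 2
        spiral_rate = float(np.polyfit(solution.z_mm[valid], folded, 1)[0])

    return {
        "peak_U0_mm_s": float(solution.U0_mm_s[i_u, j_u]),
        "peak_U0_z_mm": float(solution.z_mm[j_u]),
        "peak_U0_t_s": float(solution.t_s[i_u]),
        "peak_wss_pa": float(tau[i_t, j_t, k_t]),
        "peak_wss_z_mm": float(solution.z_mm[j_t]),
        "peak_wss_s_rad": float(s[k_t]),
        "peak_wss_t_s": float(solution.t_s[i_t]),
        "wss_map": wss_map,
        "wss_s_grid": s,
        "wss_z_grid": solution.z_mm,
        "ridge_angle_rad": ridge_lab,
        "spiral_rate_rad_per_mm": spiral_rate,
        "spiral_rate_deg_per_um": float(np.rad2deg(spiral_rate) * 1e-3)
        if np.isfinite(spiral_rate) else np.nan,
    }


def compare_with_doppler(solution: FlowSolution, doppler_series,
                         z_plane_mm: float) -> dict:
    """Relative RMS residual between the model centerline velocity and a
    Doppler-extracted series at one plane, over valid (open, unflagged)
    samples of the shared cycle window."""
    u_model = solution.centerline_velocity_at(z_plane_mm)
    sol_phase = solution.phases
    d_phase = np.mod(np.asarray(doppler_series.times_s) / solution.period_s, 1.0)
    valid = doppler_series.valid
    if not np.any(valid):
        raise ValueError("no valid Doppler samples to compare")
    order = np.argsort(d_phase[valid])
    xp = d_phase[valid][order]
    fp = np.abs(doppler_series.velocity_mm_s[valid][order])
    in_support = (sol_phase >= xp[0]) & (sol_phase <= xp[-1])
    # do not interpolate across gaps left by masked/plateau samples
    if xp.size >= 3:
        max_gap = 2.0 * np.median(np.diff(xp))
        near = np.min(np.abs(sol_phase[:, None] - xp[None, :]), axis=1)
        in_support &= near <= max_gap
    if not np.any(in_support):
        raise ValueError("model window and Doppler series do not overlap")
    v_doppler = np.interp(sol_phase[in_support], xp, fp)
    v_model = np.abs(u_model[in_support])
    peak = max(np.max(np.abs(v_model)), 1e-12)
    resid = np.sqrt(np.mean((v_model - v_doppler) ** 2)) / peak
    return {"relative_rms": float(resid), "n_samples": int(in_support.sum()),
            "peak_model_mm_s": float(np.max(np.abs(v_model))),
            "peak_doppler_mm_s": float(np.max(v_doppler))}
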