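"""Synchronize unsynchronized per-plane image sequences into one canonical
cardiac cycle, and extract M-mode / M-phase kymographs.

Acquisition of the per-plane sequences is not cardiac-gated, so each plane
starts at a random phase of the cycle.  A scalar *activity* signal (mean
absolute frame-to-frame intensity difference) is periodic at the heart rate;
its autocorrelation gives the period and circular cross-correlation between
planes gives the relative phase lags.  Each plane is then folded over its
cycles onto a uniform phase grid (196 phases by default).  The measured lag
between planes contains both the acquisition start offset and the genuine
peristaltic propagation delay; when the wave delay is known (phantom) or
modelled, passing it to :func:`synchronize` retains the peristaltic ordering
of the planes in canonical time instead of flattening it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .phantom import ImageSequence

__all__ = [
    "PeriodEstimationError",
    "activity_signal",
    "estimate_period",
    "estimate_phase_lag",
    "synchronize",
    "SyncResult",
    "extract_mmode",
    "lumen_proxy_signal",
]


class PeriodEstimationError(RuntimeError):
    """No periodic structure found in the activity signal."""


def activity_signal(seq: ImageSequence | np.ndarray) -> np.ndarray:
    """Mean absolute temporal intensity difference, one value per frame pair.

    Intensity-offset invariant and cheap; large while the wall moves, ~0 on
    the closed plateau.
    """
    frames = seq.frames if isinstance(seq, ImageSequence) else np.asarray(seq)
    return np.abs(np.diff(frames.astype(np.float64), axis=0)).mean(axis=(1, 2))


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def estimate_period(seq: ImageSequence | np.ndarray, min_lag: int = 4,
                    threshold: float = 0.2) -> float:
    """Cardiac period in frames (possibly fractional) from the activity signal.

    The period is the lag of the dominant autocorrelation peak, refined by
    parabolic interpolation; among peaks within 5% of the dominant one the
    smallest lag is taken (the fundamental rather than a multiple).  Raises
    :class:`PeriodEstimationError` when no peak rises above ``threshold``
    times the zero-lag value.
    """
    if isinstance(seq, ImageSequence) or (np.ndim(seq) == 3):
        sig = activity_signal(seq)
    else:
        sig = np.asarray(seq, dtype=float)
    sig = sig - sig.mean()
    n = sig.size
    if n < 2 * min_lag or not np.any(sig):
        raise PeriodEstimationError("signal too short or constant")
    ac = np.correlate(sig, sig, mode="full")[n - 1:]
    if ac[0] <= 0:
        raise PeriodEstimationError("degenerate autocorrelation")
    ac = ac / ac[0]
    peaks, props = find_peaks(ac[min_lag:], height=threshold)
    if peaks.size == 0:
        raise PeriodEstimationError("no periodic structure in activity signal")
    peaks = peaks + min_lag
    best = np.max(ac[peaks])
    candidates = peaks[ac[peaks] >= 0.95 * best]
    p0 = int(candidates.min())
    return _parabolic_refine(ac, p0)


def _fold_signal(sig: np.ndarray, period: float, nbins: int) -> np.ndarray:
    """Bin-average a signal onto a phase grid; empty bins filled circularly."""
    phases = np.mod(np.arange(sig.size) / period, 1.0)
    bins = np.minimum((phases * nbins).astype(int), nbins - 1)
    acc = np.bincount(bins, weights=sig, minlength=nbins)
    cnt = np.bincount(bins, minlength=nbins).astype(float)
    out = np.full(nbins, np.nan)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz]
    if not nz.all():
        grid = np.arange(nbins)
        out = np.interp(grid, grid[nz], out[nz], period=nbins)
    return out


def estimate_phase_lag(ref: ImageSequence | np.ndarray,
                       other: ImageSequence | np.ndarray,
                       period_frames: float, nbins: int = 256) -> float:
    """Phase lag of ``other`` relative to ``ref`` in frames, in [0, period).

    Both activity signals are folded onto a fine phase grid and circularly
    cross-correlated; the argmax is refined by parabolic interpolation.
    Raises :class:`PeriodEstimationError` on flat signals.
    """
    a = activity_signal(ref) if not (np.ndim(ref) == 1) else np.asarray(ref, float)
    b = activity_signal(other) if not (np.ndim(other) == 1) else np.asarray(other, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise PeriodEstimationError("flat activity signal; cannot estimate lag")
    fa = _fold_signal(a, period_frames, nbins)
    fb = _fold_signal(b, period_frames, nbins)
    fa = fa - fa.mean()
    fb = fb - fb.mean()
    # xc[m] = sum_j fa[j] * fb[j + m]: the argmax m is the phase advance of
    # the reference relative to the other plane, i.e. the other plane's lag
    xc = np.real(np.fft.ifft(np.conj(np.fft.fft(fa)) * np.fft.fft(fb)))
    k = int(np.argmax(xc))
    ext = np.array([xc[(k - 1) % nbins], xc[k], xc[(k + 1) % nbins]])
    kref = k + (_parabolic_refine(ext, 1) - 1.0)
    lag = np.mod(kref / nbins, 1.0) * period_frames
    return float(lag)


@dataclass
class SyncResult:
    """Per-plane sequences folded onto one canonical cardiac cycle."""

    period_frames: float
    lags_frames: np.ndarray            # per plane, relative to plane 0
    n_phases: int
    phases: np.ndarray                 # uniform grid in [0, 1)
    intensity: np.ndarray              # (n_planes, n_phases, rows, cols)
    phase_channel: np.ndarray | None   # same shape, wrapped Doppler phase
    frame_rate_hz: float
    pixel_pitch_um: float
    origin_shift_phases: int = 0       # applied so phase 0 = most-constricted


def _fold_stack(frames: np.ndarray, frame_phases: np.ndarray, n_phases: int,
                circular: bool = False) -> np.ndarray:
    """Median-fold frames into phase bins; empty bins interpolated.

    ``circular`` folds a wrapped-phase channel through complex phasors so the
    median respects the (-pi, pi] topology.
    """
    bins = np.minimum((np.mod(frame_phases, 1.0) * n_phases).astype(int),
                      n_phases - 1)
    shape = frames.shape[1:]
    if circular:
        data = np.exp(1j * frames.astype(np.float64))
    else:
        data = frames.astype(np.float64)
    out = np.zeros((n_phases,) + shape, dtype=complex if circular else float)
    filled = np.zeros(n_phases, dtype=bool)
    for b in range(n_phases):
        sel = bins == b
        if np.any(sel):
            if circular:
                out[b] = data[sel].mean(axis=0)
            else:
                out[b] = np.median(data[sel], axis=0)
            filled[b] = True
    if not filled.all():
        grid = np.arange(n_phases)
        src = grid[filled]
        for b in grid[~filled]:
            # circular linear interpolation between nearest filled bins
            nxt = src[np.searchsorted(src, b) % src.size]
            prv = src[(np.searchsorted(src, b) - 1) % src.size]
            d_prev = (b - prv) % n_phases
            d_next = (nxt - b) % n_phases
            w = d_prev / (d_prev + d_next)
            out[b] = (1.0 - w) * out[prv] + w * out[nxt]
    if circular:
        return np.angle(out)
    return out


def lumen_proxy_signal(intensity: np.ndarray, patch_px: int = 7) -> np.ndarray:
    """Mean intensity of a central patch per phase: low when the lumen is
    closed (dark jelly fills the centre), high when open (mid-level blood)."""
    n = intensity.shape[-1]
    c0 = n // 2 - patch_px // 2
    sl = slice(c0, c0 + patch_px)
    return intensity[..., sl, sl].mean(axis=(-1, -2))


def _plateau_center(signal: np.ndarray, frac: float = 0.05) -> int:
    """Circular centre of the near-minimum plateau of a periodic signal."""
    lo, hi = signal.min(), signal.max()
    sel = signal <= lo + frac * (hi - lo)
    ang = 2.0 * np.pi * np.arange(signal.size) / signal.size
    mean_ang = np.angle(np.sum(np.exp(1j * ang[sel])))
    return int(np.round(np.mod(mean_ang / (2.0 * np.pi), 1.0) * signal.size)) \
        % signal.size


def synchronize(sequences: list[ImageSequence], lags_frames: np.ndarray,
                period_frames: float, n_phases: int = 196,
                wave_delay_frames: np.ndarray | None = None,
                set_origin: bool = True) -> SyncResult:
    """Fold all planes onto a common ``n_phases`` cycle.

    Each plane is circularly shifted by its measured lag; if
    ``wave_delay_frames`` is given, the per-plane peristaltic delay is added
    back so the canonical cycle preserves the proximal-to-distal wave instead
    of aligning all planes' activity.  Frames are folded across cycles with a
    per-phase-bin median (phasor mean for the wrapped Doppler channel), and
    the global phase origin is set to the most-constricted state of plane 0
    (minimum of the central lumen-proxy signal).
    """
    if len({s.frame_rate_hz for s in sequences}) != 1:
        raise ValueError("all planes must share one frame rate")
    lags = np.asarray(lags_frames, dtype=float)
    if lags.size != len(sequences):
        raise ValueError("one lag per plane required")
    if wave_delay_frames is None:
        delays = np.zeros_like(lags)
    else:
        delays = np.asarray(wave_delay_frames, dtype=float)
    nominal = sequences[0].frames.shape[1:]
    npl = len(sequences)
    intensity = np.zeros((npl, n_phases) + nominal)
    has_phase = all(s.phase is not None for s in sequences)
    phase_channel = np.zeros_like(intensity) if has_phase else None
    for i, seq in enumerate(sequences):
        offset = -lags[i] + (delays[i] - delays[0])
        fr_phase = (np.arange(seq.n_frames) + offset) / period_frames
        intensity[i] = _fold_stack(seq.frames, fr_phase, n_phases)
        if has_phase:
            phase_channel[i] = _fold_stack(seq.phase, fr_phase, n_phases,
                                           circular=True)
    shift = 0
    if set_origin:
        proxy = lumen_proxy_signal(intensity[0])
        shift = _plateau_center(proxy)
        intensity = np.roll(intensity, -shift, axis=1)
        if has_phase:
            phase_channel = np.roll(phase_channel, -shift, axis=1)
    return SyncResult(
        period_frames=float(period_frames), lags_frames=lags,
        n_phases=n_phases, phases=np.arange(n_phases) / n_phases,
        intensity=intensity, phase_channel=phase_channel,
        frame_rate_hz=sequences[0].frame_rate_hz,
        pixel_pitch_um=sequences[0].pixel_pitch_um,
        origin_shift_phases=shift)


def extract_mmode(seq: ImageSequence | np.ndarray, line, n_samples: int | None = None,
                  channel: str = "intensity") -> np.ndarray:
    """Kymograph: image values along a pixel segment (space) against time.

    ``line`` is ((row0, col0), (row1, col1)) in pixel coordinates; values are
    sampled with linear interpolation.  Works on the intensity or the phase
    channel; for phase the interpolation is performed on complex phasors so
    wrapped values stay in (-pi, pi].
    """
    from scipy.ndimage import map_coordinates

    if isinstance(seq, ImageSequence):
        frames = seq.frames if channel == "intensity" else seq.phase
        if frames is None:
            raise ValueError(f"sequence has no {channel} channel")
    else:
        frames = np.asarray(seq)
    (r0, c0), (r1, c1) = line
    nr, nc = frames.shape[1:]
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= nr - 1 and 0 <= c <= nc - 1):
            raise ValueError("M-mode line endpoint outside the image")
    if n_samples is None:
        n_samples = int(np.hypot(r1 - r0, c1 - c0)) + 1
    rows = np.linspace(r0, r1, n_samples)
    cols = np.linspace(c0, c1, n_samples)
    out = np.empty((n_samples, frames.shape[0]))
    is_phase = channel == "phase"
    for t in range(frames.shape[0]):
        if is_phase:
            re = map_coordinates(np.cos(frames[t]), [rows, cols], order=1)
            im = map_coordinates(np.sin(frames[t]), [rows, cols], order=1)
            out[:, t] = np.arctan2(im, re)
        else:
            out[:, t] = map_coordinates(frames[t].astype(float), [rows, cols],
                                        order=1)
    return out
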