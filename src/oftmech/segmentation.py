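"""Active-contour segmentation of the OFT wall layers.

Three closed boundaries are delineated per cross-sectional frame: the outer
and inner myocardial contours (the bright ring) and the endocardium, i.e.
the lumen-wall interface (the mid-level region inside the ring — endocardium
and stagnant blood share the same backscatter level, so the slit boundary at
full closure is retained as the endocardial contour).

The refinement step is a classic parametric snake: internal bending/stretch
energy (weights alpha, beta) discretized as a cyclic pentadiagonal system and
solved implicitly, plus an external force that is the gradient of the squared
gradient magnitude of the Gaussian-smoothed image, diffused with a broad
Gaussian so the capture range extends away from edges (a cheap stand-in for
gradient-vector-flow diffusion).  Initialization comes from thresholded layer
masks on an attenuation-compensated image, or from the previous frame's
contour when propagating through time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.linalg import circulant
from skimage import measure

from .config import SegmentationConfig

__all__ = [
    "Contour",
    "ContourSeries",
    "SegmentationError",
    "segment_frame",
    "propagate_contours",
    "compute_centerline",
    "select_cross_sections",
    "Centerline",
    "compensate_attenuation",
]

LABELS = ("myo_outer", "myo_inner", "endo")


class SegmentationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# contours


def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Closed planar polygon in pixel coordinates (x = col, y = row).

    Vertices are stored counter-clockwise in image coordinates without
    repeating the first point; physical coordinates follow from
    ``pixel_pitch_um``.
    """

    vertices_px: np.ndarray
    label: str
    frame: int = 0
    plane_id: int = 0
    pixel_pitch_um: float = 5.0
    degenerate: bool = False   # closed-lumen slit, not a resolvable boundary

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_px, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >= 3 (x, y) vertices")
        if _polygon_area(v) < 0:  # enforce counter-clockwise orientation
            v = v[::-1]
        self.vertices_px = v

    @property
    def n_vertices(self) -> int:
        return self.vertices_px.shape[0]

    @property
    def vertices_mm(self) -> np.ndarray:
        return self.vertices_px * (self.pixel_pitch_um * 1e-3)

    @property
    def area_mm2(self) -> float:
        return abs(_polygon_area(self.vertices_mm))

    @property
    def perimeter_mm(self) -> float:
        v = self.vertices_mm
        return float(np.sum(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)))

    @property
    def centroid_px(self) -> np.ndarray:
        return self.vertices_px.mean(axis=0)

    def resample(self, n: int) -> "Contour":
        """Uniform arc-length resampling to ``n`` vertices."""
        v = self.vertices_px
        closed = np.vstack([v, v[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total == 0:
            raise SegmentationError("degenerate contour: zero perimeter")
        target = np.linspace(0.0, total, n, endpoint=False)
        x = np.interp(target, s, closed[:, 0])
        y = np.interp(target, s, closed[:, 1])
        return replace(self, vertices_px=np.column_stack([x, y]))


@dataclass
class ContourSeries:
    """One contour per label per frame for a single plane."""

    plane_id: int
    pixel_pitch_um: float
    contours: dict[str, list[Contour]] = field(default_factory=dict)

    def add(self, c: Contour) -> None:
        self.contours.setdefault(c.label, []).append(c)

    def n_frames(self, label: str) -> int:
        return len(self.contours.get(label, []))

    def areas_mm2(self, label: str) -> np.ndarray:
        return np.array([c.area_mm2 for c in self.contours[label]])

    def perimeters_mm(self, label: str) -> np.ndarray:
        return np.array([c.perimeter_mm for c in self.contours[label]])

    def check_nesting(self, atol_mm2: float = 1e-6) -> bool:
        """area(myo_outer) > area(myo_inner) >= area(endo) every frame."""
        ao = self.areas_mm2("myo_outer")
        ai = self.areas_mm2("myo_inner")
        ae = self.areas_mm2("endo")
        return bool(np.all(ao > ai) and np.all(ai >= ae - atol_mm2))


# ---------------------------------------------------------------------------
# preprocessing


def compensate_attenuation(frame: np.ndarray, background: float = 0.1) -> np.ndarray:
    """Undo exponential depth attenuation along the beam (row) axis.

    A log-linear model is fitted to the row-wise upper-decile intensity over
    rows that contain tissue, and the image is divided by the fitted decay.
    """
    frame = np.asarray(frame, dtype=float)
    prof = np.quantile(frame, 0.9, axis=1)
    rows = np.flatnonzero(prof > background)
    if rows.size < 8:
        return frame
    coef = np.polyfit(rows, np.log(prof[rows]), 1)
    slope = min(coef[0], 0.0)  # attenuation only ever darkens with depth
    decay = np.exp(slope * (np.arange(frame.shape[0]) - rows[0]))
    return frame / np.maximum(decay, 1e-3)[:, None]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _mask_to_contour(mask: np.ndarray, n_vertices: int, label: str,
                     pitch: float, **kw) -> Contour:
    padded = np.pad(mask.astype(float), 1)
    lines = measure.find_contours(padded, 0.5)
    if not lines:
        raise SegmentationError(f"no boundary found for {label}")
    line = max(lines, key=len) - 1.0  # remove padding offset; (row, col)
    verts = np.column_stack([line[:, 1], line[:, 0]])  # -> (x, y)
    c = Contour(vertices_px=verts, label=label, pixel_pitch_um=pitch, **kw)
    return c.resample(n_vertices)


def _layer_masks(frame: np.ndarray, cfg: SegmentationConfig):
    """Threshold-based masks for the myocardial ring and the lumen region.

    The band of smoothed intermediate intensities where the dark jelly meets
    the bright myocardium would alias into the lumen window, so the interior
    is eroded by roughly the smoothing scale before the lumen mask is taken.
    """
    comp = compensate_attenuation(frame)
    smooth = ndimage.gaussian_filter(comp, cfg.sigma_px)
    # a lighter blur for the masks keeps thin (few-pixel) myocardial rings
    # above threshold; speckle holes in the ring are closed morphologically
    mask_img = ndimage.gaussian_filter(comp, max(cfg.sigma_px / 2.0, 0.8))
    ring = ndimage.binary_closing(mask_img > cfg.myo_threshold, iterations=2)
    ring = _largest_component(ring)
    disk = ndimage.binary_fill_holes(ring)
    inner = _largest_component(disk & ~ring)
    inner = ndimage.binary_fill_holes(inner)
    core = ndimage.binary_erosion(inner, iterations=max(int(cfg.sigma_px) + 1, 1))
    lumen = (mask_img > cfg.lumen_low) & (mask_img < cfg.lumen_high) & core
    lumen = ndimage.binary_opening(lumen, iterations=1)
    if np.any(lumen):
        lumen = _largest_component(lumen)
    return smooth, disk, inner, lumen


# ---------------------------------------------------------------------------
# snake


def _snake_matrix(n: int, cfg: SegmentationConfig) -> np.ndarray:
    a, b = cfg.beta, -cfg.alpha - 4.0 * cfg.beta
    c = 2.0 * cfg.alpha + 6.0 * cfg.beta
    row = np.zeros(n)
    row[0], row[1], row[2], row[-2], row[-1] = c, b, a, a, b
    return np.linalg.inv(np.eye(n) + cfg.gamma * circulant(row))


def _external_force(image: np.ndarray, cfg: SegmentationConfig,
                    force_sigma: float | None = None,
                    pre_sigma: float | None = None):
    pre = cfg.sigma_px if pre_sigma is None else pre_sigma
    smooth = ndimage.gaussian_filter(np.asarray(image, dtype=float), pre) \
        if pre > 0 else np.asarray(image, dtype=float)
    gy, gx = np.gradient(smooth)
    edge = gx**2 + gy**2
    fy, fx = np.gradient(edge)
    # diffuse the force field to extend the capture range
    sigma = cfg.force_sigma_px if force_sigma is None else force_sigma
    fx = ndimage.gaussian_filter(fx, sigma)
    fy = ndimage.gaussian_filter(fy, sigma)
    scale = max(np.max(np.hypot(fx, fy)), 1e-12)
    return fx / scale, fy / scale


def _evolve_snake(init_xy: np.ndarray, force, cfg: SegmentationConfig) -> np.ndarray:
    fx, fy = force
    n = init_xy.shape[0]
    inv = _snake_matrix(n, cfg)
    xy = init_xy.copy()
    shape = fx.shape
    for _ in range(cfg.max_iter):
        cols = np.clip(xy[:, 0], 0, shape[1] - 1)
        rows = np.clip(xy[:, 1], 0, shape[0] - 1)
        coords = [rows, cols]
        ex = ndimage.map_coordinates(fx, coords, order=1)
        ey = ndimage.map_coordinates(fy, coords, order=1)
        new = inv @ (xy + cfg.gamma * cfg.kappa * np.column_stack([ex, ey]))
        disp = np.max(np.linalg.norm(new - xy, axis=1))
        xy = new
        if disp < cfg.tol_px:
            break
    return xy


def segment_frame(image: np.ndarray, init: Contour | None = None,
                  label: str = "myo_inner",
                  cfg: SegmentationConfig | None = None,
                  frame: int = 0, plane_id: int = 0,
                  pixel_pitch_um: float = 5.0) -> Contour:
    """Delineate one boundary in one intensity frame.

    Without ``init`` the contour is seeded from thresholded layer masks; with
    ``init`` (e.g. the previous frame's contour) the snake starts there.  For
    ``label='endo'`` with a closed lumen the slit boundary of the residual
    mid-level region is returned and flagged ``degenerate``.
    """
    cfg = cfg or SegmentationConfig()
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    smooth, disk, inner, lumen = _layer_masks(image, cfg)
    if label == "endo":
        n_lumen = int(np.count_nonzero(lumen))
        if n_lumen < cfg.min_lumen_px:
            if not np.any(inner) and init is not None and not init.degenerate:
                # frame dropout (broken ring), not a closure: keep the
                # propagated contour instead of collapsing to a slit
                return replace(init, frame=frame)
            return _slit_contour(inner, cfg, init=init, frame=frame,
                                 plane_id=plane_id, pitch=pixel_pitch_um)
        mask = lumen
    elif label == "myo_outer":
        if not np.any(disk) and init is None:
            raise SegmentationError("no myocardial ring found")
        mask = disk
    else:
        # a broken thin ring can lose its interior in single frames; the
        # propagated contour then carries the snake on its own
        if not np.any(inner) and init is None:
            raise SegmentationError("no inner myocardial region found")
        mask = inner

    if init is not None:
        seed = init.resample(cfg.n_vertices).vertices_px
    else:
        seed = _mask_to_contour(mask, cfg.n_vertices, label,
                                pixel_pitch_um).vertices_px
    if label == "endo":
        # region force from the classified lumen mask: its only gradient is
        # the lumen boundary, so the snake is neither captured by the much
        # stronger jelly-myocardium edge nor biased by speckle inside the
        # lumen, and merely regularizes the classification boundary
        feature = ndimage.gaussian_filter(mask.astype(float), 1.5)
        force = _external_force(feature, cfg, force_sigma=1.5, pre_sigma=0.0)
    else:
        # light smoothing and short diffusion keep the two edges of a thin
        # myocardial ring from merging and the inner boundary from being
        # captured by the far stronger myocardium-background edge
        force = _external_force(smooth, cfg, force_sigma=cfg.force_sigma_px / 3.0,
                                pre_sigma=cfg.sigma_px / 2.0)
    xy = _evolve_snake(seed, force, cfg)
    c = Contour(vertices_px=xy, label=label, frame=frame, plane_id=plane_id,
                pixel_pitch_um=pixel_pitch_um)
    # a propagated init can carry over an error from a corrupted frame; when
    # the result disagrees strongly with the mask evidence, restart from it
    if init is not None and np.any(mask):
        mask_area = float(np.count_nonzero(mask)) * (pixel_pitch_um * 1e-3) ** 2
        if mask_area > 0 and abs(c.area_mm2 - mask_area) > 0.2 * mask_area:
            seed = _mask_to_contour(mask, cfg.n_vertices, label,
                                    pixel_pitch_um).vertices_px
            xy = _evolve_snake(seed, force, cfg)
            c = Contour(vertices_px=xy, label=label, frame=frame,
                        plane_id=plane_id, pixel_pitch_um=pixel_pitch_um)
    return c


def _slit_contour(inner_mask, cfg, init, frame, plane_id, pitch) -> Contour:
    """Closed-lumen fallback: a flat slit polygon.

    The cushions appose along the lumen's minor axis, so the slit lies along
    the last open lumen's major axis when a propagated contour is available;
    otherwise it is placed at the centroid of the inner myocardial region
    (the true slit is invisible — endocardium and stagnant blood share one
    intensity level)."""
    if init is not None and init.n_vertices >= 3 and init.area_mm2 > 0:
        center = init.centroid_px
        pts = init.vertices_px - center
        u, _, _ = np.linalg.svd(pts.T @ pts)
        axis = u[:, 0]
        half = float(np.abs(pts @ axis).max())
        cx, cy = center
    elif np.any(inner_mask):
        rows, cols = np.nonzero(inner_mask)
        cy, cx = rows.mean(), cols.mean()
        axis = np.array([1.0, 0.0])
        half = 0.5 * np.sqrt(rows.size / np.pi)
    else:
        raise SegmentationError("no interior region for slit contour")
    half = max(half, 1.0)
    t = np.linspace(0, 2 * np.pi, cfg.n_vertices, endpoint=False)
    ex = half * np.cos(t)
    ey = 0.25 * np.sin(t)  # quarter-pixel thickness: area ~ 0
    rot = np.column_stack([ex * axis[0] - ey * axis[1],
                           ex * axis[1] + ey * axis[0]])
    verts = rot + np.array([cx, cy])
    return Contour(vertices_px=verts, label="endo", frame=frame,
                   plane_id=plane_id, pixel_pitch_um=pitch, degenerate=True)


def propagate_contours(frames: np.ndarray, labels=LABELS,
                       cfg: SegmentationConfig | None = None,
                       plane_id: int = 0, pixel_pitch_um: float = 5.0,
                       max_area_jump: float = 0.5) -> ContourSeries:
    """Segment a full sequence, initializing each frame from the previous one.

    A coarse global displacement between consecutive frames (phase
    cross-correlation) warps the previous contour before snake refinement.
    If the enclosed area jumps by more than ``max_area_jump`` relative to the
    previous frame, the frame is re-segmented from scratch; if that also
    fails, a :class:`SegmentationError` reports the frame index.
    """
    from skimage.registration import phase_cross_correlation

    cfg = cfg or SegmentationConfig()
    frames = np.asarray(frames)
    series = ContourSeries(plane_id=plane_id, pixel_pitch_um=pixel_pitch_um)
    prev: dict[str, Contour] = {}
    prev_frame = None
    for t in range(frames.shape[0]):
        img = frames[t]
        shift = np.zeros(2)
        if prev_frame is not None:
            try:
                shift, _, _ = phase_cross_correlation(prev_frame, img,
                                                      upsample_factor=4,
                                                      normalization=None)
            except Exception:
                shift = np.zeros(2)
        for label in labels:
            init = None
            if label in prev and not prev[label].degenerate:
                warped = prev[label].vertices_px - shift[::-1]  # (dy,dx)->(dx,dy)
                init = replace(prev[label], vertices_px=warped)
            try:
                c = segment_frame(img, init=init, label=label, cfg=cfg,
                                  frame=t, plane_id=plane_id,
                                  pixel_pitch_um=pixel_pitch_um)
                if (init is not None and not c.degenerate and init.area_mm2 > 0
                        and abs(c.area_mm2 - prev[label].area_mm2)
                        > max_area_jump * max(prev[label].area_mm2, 1e-9)):
                    c = segment_frame(img, init=None, label=label, cfg=cfg,
                                      frame=t, plane_id=plane_id,
                                      pixel_pitch_um=pixel_pitch_um)
            except SegmentationError as err:
                raise SegmentationError(f"frame {t}, label {label}: {err}") from err
            series.add(c)
            prev[label] = c
        prev_frame = img
    if set(labels) >= {"myo_outer", "myo_inner", "endo"} and not series.check_nesting():
        warnings.warn("contour nesting violated in at least one frame",
                      stacklevel=2)
    return series


# ---------------------------------------------------------------------------
# centerline


@dataclass
class Centerline:
    """Smooth curve through the section centers, proximal to distal."""

    points_mm: np.ndarray   # (n, 3): x, y, z
    arc_length_mm: float
    tangents: np.ndarray    # (n, 3) unit vectors

    def at_arc_length(self, s: np.ndarray) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        out = np.empty((np.size(s), 3))
        for j in range(3):
            out[:, j] = np.interp(s, cum, self.points_mm[:, j])
        return out


def compute_centerline(sections: list[tuple[float, Contour]],
                       n_samples: int = 200) -> Centerline:
    """Centerline through inner-myocardial centroids at the most-constricted
    phase.  ``sections`` is a list of (z position in um, myo_inner contour)
    ordered proximal to distal."""
    if len(sections) < 2:
        raise ValueError("need at least two planes for a centerline")
    z = np.array([s[0] for s in sections], dtype=float) * 1e-3  # mm
    centers = np.array([c.centroid_px * (c.pixel_pitch_um * 1e-3)
                        for _, c in sections])
    if len(sections) >= 4:
        from scipy.interpolate import CubicSpline
        zs = np.linspace(z[0], z[-1], n_samples)
        x = CubicSpline(z, centers[:, 0])(zs)
        y = CubicSpline(z, centers[:, 1])(zs)
    else:
        zs = np.linspace(z[0], z[-1], n_samples)
        x = np.interp(zs, z, centers[:, 0])
        y = np.interp(zs, z, centers[:, 1])
    pts = np.column_stack([x, y, zs])
    seg = np.diff(pts, axis=0)
    arc = float(np.sum(np.linalg.norm(seg, axis=1)))
    tang = np.vstack([seg, seg[-1:]])
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    return Centerline(points_mm=pts, arc_length_mm=arc, tangents=tang)


def select_cross_sections(centerline: Centerline, n: int = 5):
    """``n`` evenly spaced points along the centerline with tangent normals."""
    if n < 2:
        raise ValueError("need at least two cross-sections")
    if centerline.arc_length_mm <= 0:
        raise ValueError("centerline has zero length")
    s = np.linspace(0.0, centerline.arc_length_mm, n)
    pts = centerline.at_arc_length(s)
    seg = np.linalg.norm(np.diff(centerline.points_mm, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    idx = np.searchsorted(cum, s, side="left").clip(0, len(cum) - 1)
    normals = centerline.tangents[idx]
    return [(pts[i], normals[i]) for i in range(n)]
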