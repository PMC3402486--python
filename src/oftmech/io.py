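"""File I/O: HDF5 phantom datasets, multi-page TIFF stacks, contour and
pressure CSVs.

Layout of the HDF5 dataset written by :func:`write_dataset`::

    /plane_<i>/intensity   (time, rows, cols) float32 in [0, 1]
    /plane_<i>/phase       optional, wrapped Doppler phase
    /truth/...             ground-truth arrays (phantom data only)

Pressure CSVs carry two columns, ``time_s`` and ``pressure_pa``; contour
CSVs one vertex per row (plane_id, frame, label, vertex_idx, x_mm, y_mm).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .phantom import GroundTruth, ImageSequence
from .segmentation import Contour, ContourSeries
from .wall_stress import PressureTrace

__all__ = [
    "write_dataset", "read_dataset",
    "write_tiff", "read_tiff",
    "write_pressure_csv", "read_pressure_csv",
    "write_contours_csv", "read_contours_csv",
    "write_sync", "read_sync",
]

_TRUTH_ARRAYS = ("start_phase", "wave_delay_cycles", "lag_frames", "phases",
                 "r_inner_mm", "r_outer_mm", "lumen_area_mm2", "jelly_area_mm2",
                 "a_mm", "b_mm", "angle_rad", "open_mask",
                 "p_vent_phase", "p_as_phase", "centerline_velocity_mm_s")


def write_dataset(path: str | Path, sequences: list[ImageSequence],
                  truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        for seq in sequences:
            g = f.create_group(f"plane_{seq.plane_id}")
            g.create_dataset("intensity", data=seq.frames, compression="gzip")
            if seq.phase is not None:
                g.create_dataset("phase", data=seq.phase, compression="gzip")
            g.attrs["pixel_pitch_um"] = seq.pixel_pitch_um
            g.attrs["frame_rate_hz"] = seq.frame_rate_hz
            g.attrs["plane_id"] = seq.plane_id
            g.attrs["beam_axis"] = seq.beam_axis
        if truth is not None:
            t = f.create_group("truth")
            for name in _TRUTH_ARRAYS:
                arr = getattr(truth, name)
                if arr is not None:
                    t.create_dataset(name, data=np.asarray(arr))
            t.attrs["period_s"] = truth.config.period_s
            t.attrs["tube_length_um"] = truth.config.tube_length_um
            t.attrs["seed"] = truth.config.seed


def read_dataset(path: str | Path) -> tuple[list[ImageSequence], dict]:
    """Read per-plane sequences and (if present) the raw truth arrays."""
    sequences = []
    truth: dict = {}
    with h5py.File(path, "r") as f:
        planes = sorted(k for k in f if k.startswith("plane_"))
        for key in sorted(planes, key=lambda k: int(k.split("_")[1])):
            g = f[key]
            sequences.append(ImageSequence(
                frames=g["intensity"][...],
                phase=g["phase"][...] if "phase" in g else None,
                pixel_pitch_um=float(g.attrs["pixel_pitch_um"]),
                frame_rate_hz=float(g.attrs["frame_rate_hz"]),
                plane_id=int(g.attrs["plane_id"]),
                beam_axis=int(g.attrs.get("beam_axis", 0))))
        if "truth" in f:
            t = f["truth"]
            truth = {name: t[name][...] for name in t}
            truth.update({k: t.attrs[k] for k in t.attrs})
    return sequences, truth


def write_tiff(path: str | Path, seq: ImageSequence, channel: str = "intensity"
               ) -> None:
    """Multi-page TIFF of one plane; phase is stored as float32 radians."""
    data = seq.frames if channel == "intensity" else seq.phase
    if data is None:
        raise ValueError(f"sequence has no {channel} channel")
    tifffile.imwrite(path, data.astype(np.float32),
                     metadata={"pixel_pitch_um": seq.pixel_pitch_um,
                               "frame_rate_hz": seq.frame_rate_hz,
                               "plane_id": seq.plane_id})


def read_tiff(path: str | Path, pixel_pitch_um: float = 5.0,
              frame_rate_hz: float = 140.0, plane_id: int = 0) -> ImageSequence:
    frames = tifffile.imread(path)
    return ImageSequence(frames=np.asarray(frames), pixel_pitch_um=pixel_pitch_um,
                         frame_rate_hz=frame_rate_hz, plane_id=plane_id)


def write_pressure_csv(path: str | Path, trace: PressureTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "pressure_pa": trace.pressure_pa}
                 ).to_csv(path, index=False)


def read_pressure_csv(path: str | Path, site: str = "ventricle") -> PressureTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 100.0
    return PressureTrace(time_s=t, pressure_pa=df["pressure_pa"].to_numpy(),
                         site=site, sampling_rate_hz=fs)


def write_contours_csv(path: str | Path,
                       series_by_plane: dict[int, ContourSeries]) -> None:
    rows = []
    for plane, series in sorted(series_by_plane.items()):
        for label, contours in series.contours.items():
            for c in contours:
                v = c.vertices_mm
                rows.append(pd.DataFrame({
                    "plane_id": plane, "frame": c.frame, "label": label,
                    "vertex_idx": np.arange(c.n_vertices),
                    "x_mm": v[:, 0], "y_mm": v[:, 1],
                    "degenerate": c.degenerate,
                }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_contours_csv(path: str | Path, pixel_pitch_um: float = 5.0
                      ) -> dict[int, ContourSeries]:
    df = pd.read_csv(path)
    out: dict[int, ContourSeries] = {}
    scale = 1.0 / (pixel_pitch_um * 1e-3)
    for plane, gp in df.groupby("plane_id"):
        series = ContourSeries(plane_id=int(plane), pixel_pitch_um=pixel_pitch_um)
        for (label, frame), gv in gp.groupby(["label", "frame"], sort=True):
            gv = gv.sort_values("vertex_idx")
            verts = np.column_stack([gv["x_mm"], gv["y_mm"]]) * scale
            series.add(Contour(vertices_px=verts, label=str(label),
                               frame=int(frame), plane_id=int(plane),
                               pixel_pitch_um=pixel_pitch_um,
                               degenerate=bool(gv["degenerate"].iloc[0])))
        # keep frame order within each label
        for label in series.contours:
            series.contours[label].sort(key=lambda c: c.frame)
        out[int(plane)] = series
    return out


def write_sync(path: str | Path, sync) -> None:
    """Canonical-cycle HDF5: per-plane folded stacks plus the sync metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=sync.intensity.astype(np.float32),
                         compression="gzip")
        if sync.phase_channel is not None:
            f.create_dataset("phase", data=sync.phase_channel.astype(np.float32),
                             compression="gzip")
        f.attrs["period_frames"] = sync.period_frames
        f.attrs["n_phases"] = sync.n_phases
        f.attrs["frame_rate_hz"] = sync.frame_rate_hz
        f.attrs["pixel_pitch_um"] = sync.pixel_pitch_um
        f.attrs["origin_shift_phases"] = sync.origin_shift_phases
        f.create_dataset("lags_frames", data=sync.lags_frames)


def read_sync(path: str | Path):
    from .reconstruction import SyncResult

    with h5py.File(path, "r") as f:
        intensity = f["intensity"][...]
        phase = f["phase"][...] if "phase" in f else None
        n_phases = int(f.attrs["n_phases"])
        return SyncResult(
            period_frames=float(f.attrs["period_frames"]),
            lags_frames=f["lags_frames"][...], n_phases=n_phases,
            phases=np.arange(n_phases) / n_phases,
            intensity=intensity, phase_channel=phase,
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            pixel_pitch_um=float(f.attrs["pixel_pitch_um"]),
            origin_shift_phases=int(f.attrs["origin_shift_phases"]))
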