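"""End-to-end pipeline: phantom -> reconstruction -> segmentation ->
kinematics -> Doppler -> wall stress -> hemodynamics -> report.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
composes them and, when an output directory is configured, writes every
intermediate artifact (HDF5 stacks, CSV tables, PNG maps) stamped with the
seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .config import RunConfig, save_run_config
from .doppler import VelocitySeries, centerline_velocity_series
from .hemodynamics import (FlowSolution, LumenModel, build_lumen_model,
                           compare_with_doppler, solve_flow, summarize)
from .kinematics import build_kinematics, summary_table
from .phantom import GroundTruth, ImageSequence, render_sequences
from .reconstruction import (SyncResult, estimate_period, estimate_phase_lag,
                             extract_mmode, synchronize)
from .segmentation import ContourSeries, propagate_contours
from .wall_stress import align_pressure_phase, stress_profile

log = logging.getLogger("oftmech")

__all__ = ["PipelineResult", "run_pipeline", "config_hash"]


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    sequences: list[ImageSequence]
    truth: GroundTruth
    sync: SyncResult
    contours: dict[int, ContourSeries]
    kinematics: pd.DataFrame
    summary: pd.DataFrame
    velocities: dict[int, VelocitySeries]
    stress: pd.DataFrame | None
    lumen_model: LumenModel | None
    flow: FlowSolution | None
    flow_summary: dict | None
    velocity_comparison: dict[int, dict] | None
    metadata: dict = field(default_factory=dict)


def _reconstruct(sequences, config: RunConfig) -> SyncResult:
    period = estimate_period(sequences[0])
    lags = np.array([estimate_phase_lag(sequences[0], s, period)
                     for s in sequences])
    delays = config.phantom.wave_delay_cycles * period
    return synchronize(sequences, lags, period, n_phases=config.n_phases,
                       wave_delay_frames=delays)


def _segment(sync: SyncResult, config: RunConfig) -> dict[int, ContourSeries]:
    out = {}
    for i in range(sync.intensity.shape[0]):
        out[i] = propagate_contours(sync.intensity[i], cfg=config.segmentation,
                                    plane_id=i,
                                    pixel_pitch_um=sync.pixel_pitch_um)
    return out


def _doppler_stage(sync: SyncResult, kin: pd.DataFrame, config: RunConfig
                   ) -> dict[int, VelocitySeries]:
    """Centerline velocity per plane from the canonical M-phase data."""
    out = {}
    if sync.phase_channel is None:
        return out
    n = sync.intensity.shape[-1]
    c = (n - 1) / 2.0
    period_s = sync.period_frames / sync.frame_rate_hz
    for i in range(sync.intensity.shape[0]):
        mphase = extract_mmode(sync.phase_channel[i], ((0, c), (n - 1, c)),
                               n_samples=n, channel="phase")
        g = kin[kin["plane"] == i].sort_values("phase_index")
        a_lumen = g["A_lumen_mm2"].to_numpy()
        rng = a_lumen.max() - a_lumen.min()
        open_mask = a_lumen > a_lumen.min() + 0.05 * max(rng, 1e-12)
        times = np.arange(sync.n_phases) / sync.n_phases * period_s
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[i] = centerline_velocity_series(
                mphase, row=int(round(c)), cfg=config.doppler,
                theta_deg=config.phantom.doppler_angle_deg[i],
                times_s=times, open_mask=open_mask)
    return out


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Run every stage on a freshly rendered phantom; see module docstring."""
    config = config or RunConfig()
    stage = "simulate"
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config_hash(config)}
    try:
        sequences, truth = render_sequences(config.phantom,
                                            include_doppler=True,
                                            n_phases=config.n_phases,
                                            flow_cfg=config.flow)
        if outdir:
            oio.write_dataset(outdir / "data.h5", sequences, truth)
            oio.write_pressure_csv(outdir / "pressure_ventricle.csv", truth.p_vent)
            oio.write_pressure_csv(outdir / "pressure_aortic_sac.csv", truth.p_as)
            save_run_config(config, outdir / "config.yaml")

        stage = "reconstruct"
        sync = _reconstruct(sequences, config)
        if outdir:
            oio.write_sync(outdir / "cycle.h5", sync)
            (outdir / "sync.json").write_text(json.dumps({
                "period_frames": sync.period_frames,
                "lags_frames": sync.lags_frames.tolist(),
                "n_phases": sync.n_phases,
                "origin_shift_phases": sync.origin_shift_phases, **meta}, indent=2))

        stage = "segment"
        contours = _segment(sync, config)
        if outdir:
            oio.write_contours_csv(outdir / "contours.csv", contours)

        stage = "kinematics"
        period_s = sync.period_frames / sync.frame_rate_hz
        kin = build_kinematics(contours, period_s)
        summary = summary_table(kin)
        if outdir:
            kin.to_csv(outdir / "kinematics.csv", index=False)
            summary.to_csv(outdir / "summary.csv", index=False)

        stage = "doppler"
        velocities = _doppler_stage(sync, kin, config)
        if outdir and velocities:
            rows = []
            for i, v in velocities.items():
                rows.append(pd.DataFrame({
                    "plane": i, "time_s": v.times_s,
                    "V_mm_s": v.velocity_mm_s, "masked": v.masked,
                    "plateau": v.plateau}))
            pd.concat(rows, ignore_index=True).to_csv(
                outdir / "velocity.csv", index=False)

        stage = "stress"
        a1 = kin[kin["plane"] == 0].sort_values("phase_index")[
            "A_lumen_mm2"].to_numpy()
        pv, _ = align_pressure_phase(truth.p_vent, a1, period_s=period_s,
                                     rule=config.pressure_alignment)
        pa, _ = align_pressure_phase(truth.p_as, a1, period_s=period_s,
                                     rule=config.pressure_alignment)
        stress = stress_profile(kin, pv, pa)
        if outdir:
            stress.to_csv(outdir / "stress.csv", index=False)

        lumen_model = flow = flow_summary = vel_cmp = None
        if config.enable_flow:
            stage = "flow"
            lumen_model = build_lumen_model(
                contours, config.phantom.z_planes_um * 1e-3, period_s,
                mu_pa_s=config.flow.mu_pa_s,
                window_cycle=config.flow.window_cycle,
                b_floor_mm=config.flow.b_floor_mm)
            if config.flow.auto_window:
                lumen_model = lumen_model.with_auto_window()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flow = solve_flow(lumen_model, pv - pa,
                                  n_steps=config.flow.n_steps,
                                  n_z=config.flow.n_z)
                flow_summary = summarize(flow, lumen_model)
            vel_cmp = {}
            for i, v in velocities.items():
                try:
                    vel_cmp[i] = compare_with_doppler(
                        flow, v, float(config.phantom.z_planes_um[i] * 1e-3))
                except ValueError:
                    continue
            if outdir:
                _write_flow_outputs(outdir, flow, flow_summary, vel_cmp)

        stage = "report"
        if outdir:
            report = {
                **meta,
                "period_frames": sync.period_frames,
                "timing_fractions": summary[
                    ["plane", "T_e_frac", "T_c_frac", "T_closure_frac"]
                ].to_dict("records"),
                "peak_stress_by_plane": stress.groupby("plane")["sigma_pa"]
                .max().to_dict(),
            }
            if flow_summary:
                report["flow"] = {k: v for k, v in flow_summary.items()
                                  if np.isscalar(v)}
            if vel_cmp:
                report["velocity_comparison"] = {
                    str(k): v for k, v in vel_cmp.items()}
            (outdir / "report.json").write_text(
                json.dumps(report, indent=2, default=float))
        return PipelineResult(
            config=config, sequences=sequences, truth=truth, sync=sync,
            contours=contours, kinematics=kin, summary=summary,
            velocities=velocities, stress=stress, lumen_model=lumen_model,
            flow=flow, flow_summary=flow_summary, velocity_comparison=vel_cmp,
            metadata=meta)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _write_flow_outputs(outdir: Path, flow: FlowSolution, flow_summary: dict,
                        vel_cmp: dict) -> None:
    import h5py

    with h5py.File(outdir / "flow.h5", "w") as f:
        for name in ("t_s", "z_mm", "Q_mm3_s", "Q0_mm3_s", "U0_mm_s",
                     "a_mm", "b_mm", "dp_pa"):
            f.create_dataset(name, data=getattr(flow, name))
    wss_map = flow_summary["wss_map"]
    dfm = pd.DataFrame(wss_map, index=flow_summary["wss_z_grid"],
                       columns=flow_summary["wss_s_grid"])
    dfm.to_csv(outdir / "wss_map.csv")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(wss_map.T, origin="lower", aspect="auto",
                       extent=[flow.z_mm[0], flow.z_mm[-1], 0, 2 * np.pi])
        ax.set_xlabel("z (mm)")
        ax.set_ylabel("ellipse parameter s (rad)")
        fig.colorbar(im, ax=ax, label="wall shear stress (Pa)")
        fig.savefig(outdir / "wss_map.png", dpi=120)
        plt.close(fig)
    except Exception:   # plotting is best-effort
        pass
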