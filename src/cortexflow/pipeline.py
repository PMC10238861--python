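"""End-to-end orchestration: configuration, seeding, stage execution,
provenance reporting and deterministic fixture generation.

A run configuration (YAML or dict) selects stages and supplies per-module
parameter blocks. The single global seed is fanned out through named
substreams, one per stage, so changing one stage's work does not perturb
another stage's randomness. Every run writes a provenance report embedding
the fully resolved configuration and the per-stage seeds.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .advection_stats import fit_advection, project_displacements
from .flow_field import FlowField, PivParams, piv
from .particle_sim import (
    ImageStack,
    SimulationConfig,
    TrajectorySet,
    render_cortex_texture,
    render_images,
    simulate_trajectories,
)
from .pde_polarity import PdeParams, compute_metrics, solve_pde, sweep
from .spot_tracking import TrackingParams, track_stack

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "stage_seed"]

_STAGE_ORDER = ["simulate", "render", "track", "piv", "advect", "pde"]
_STAGE_INDEX = {name: i for i, name in enumerate(_STAGE_ORDER + ["fixtures"])}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2^31)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_INDEX.get(stage, 99)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Resolved pipeline configuration."""

    stages: list[str]
    out_dir: Path
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    piv: dict = field(default_factory=dict)
    pde: dict = field(default_factory=dict)
    advection: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self.stages = [s for s in _STAGE_ORDER if s in self.stages]
        self.out_dir = Path(self.out_dir)
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input '{name}' not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def resolved(self) -> dict:
        return {
            "stages": self.stages,
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "stage_seeds": {s: stage_seed(self.seed, s) for s in self.stages},
            "simulation": self.simulation,
            "tracking": self.tracking,
            "piv": self.piv,
            "pde": self.pde,
            "advection": self.advection,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "version": __version__,
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Writes intermediate files and a provenance report under
    ``config.out_dir``; a stage failure halts its dependents but the
    report (with per-stage status) is always written. Returns the report.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.resolved(), "stages": {}}
    artifacts: dict = {}

    def record(stage: str, status: str, **extra) -> None:
        report["stages"][stage] = {"status": status, **extra}

    failed = False
    for stage in config.stages:
        if failed:
            record(stage, "skipped", reason="upstream failure")
            continue
        try:
            if stage == "simulate":
                sim_cfg = SimulationConfig.from_dict(
                    {**config.simulation, "seed": stage_seed(config.seed, "simulate")})
                traj, truth = simulate_trajectories(sim_cfg)
                traj.to_csv(out / "trajectories.csv")
                truth.to_csv(out / "ground_truth.csv", index=False)
                artifacts["traj"] = traj
                artifacts["sim_cfg"] = sim_cfg
                record(stage, "ok", n_particles=sim_cfg.n_particles,
                       n_rows=len(traj))
            elif stage == "render":
                sim_cfg = artifacts["sim_cfg"]
                stack = render_images(artifacts["traj"], sim_cfg)
                stack.to_tiff(out / "particles.tif")
                artifacts["stack"] = stack
                record(stage, "ok", shape=list(stack.shape))
            elif stage == "track":
                if "stack" in artifacts:
                    stack = artifacts["stack"]
                else:
                    stack = ImageStack.from_tiff(config.inputs["stack"])
                params = TrackingParams(**config.tracking)
                tracked = track_stack(stack, params)
                tracked.to_csv(out / "tracks.csv")
                artifacts["tracked"] = tracked
                record(stage, "ok", n_tracks=tracked.n_particles)
            elif stage == "piv":
                if "cortex" in config.inputs:
                    stack = ImageStack.from_tiff(config.inputs["cortex"])
                else:
                    stack = artifacts["stack"]
                flow = piv(stack, PivParams(**config.piv))
                flow.to_csv(out / "flow.csv")
                artifacts["flow"] = flow
                record(stage, "ok", n_vectors=int(np.prod(flow.vx.shape)))
            elif stage == "advect":
                traj = artifacts.get("tracked") or artifacts.get("traj")
                if traj is None:
                    traj = TrajectorySet.from_csv(config.inputs["tracks"])
                flow = artifacts.get("flow")
                if flow is None:
                    flow = FlowField.from_csv(config.inputs["flow"])
                adv = dict(config.advection)
                tau = adv.pop("tau_frames", 5)
                samples = project_displacements(traj, flow, tau_frames=tau)
                est = fit_advection(samples, **adv)
                samples.to_csv(out / "displacements.csv", index=False)
                (out / "advection.json").write_text(json.dumps(est.to_dict(), indent=1))
                record(stage, "ok", **est.to_dict())
            elif stage == "pde":
                params = PdeParams(**config.pde)
                sol = solve_pde(params)
                metrics = compute_metrics(sol)
                summary = {
                    "peak_asi": metrics.peak_asi,
                    "peak_depletion": metrics.peak_depletion,
                    "t_half_asi_s": metrics.t_half_asi,
                    "t_half_depletion_s": metrics.t_half_depletion,
                    "asi_post300": metrics.asi_post300,
                    "depletion_post300": metrics.depletion_post300,
                }
                (out / "pde_metrics.json").write_text(json.dumps(summary, indent=1))
                pd.DataFrame({"t_s": metrics.times, "asi": metrics.asi,
                              "depletion": metrics.depletion}).to_csv(
                    out / "pde_timeseries.csv", index=False)
                record(stage, "ok", **summary)
        except Exception as err:  # noqa: BLE001 - stage status is the contract
            record(stage, "failed", error=str(err))
            failed = True

    report["status"] = "failed" if failed else "ok"
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def phase_diagram_sweep(out_dir, n: int = 12, params: Optional[PdeParams] = None) -> pd.DataFrame:
    """Phase-diagram preset: n×n log grid of D ∈ [1e-3, 10] µm²/s and
    k_off ∈ [1e-4, 1] s⁻¹; writes the four surfaces as CSV."""
    D_grid = np.logspace(-3, 1, n)
    k_grid = np.logspace(-4, 0, n)
    df = sweep(D_grid, k_grid, params)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "phase_diagram.csv", index=False)
    for col in ("peak_asi", "peak_depletion", "t_half_asi", "t_half_depletion"):
        df.pivot(index="D_um2_s", columns="k_off_s", values=col).to_csv(
            out / f"{col}_grid.csv")
    return df


def make_fixtures(kind: str, seed: int = 0, out_dir=None) -> dict:
    """Small deterministic datasets with ground truth for validation.

    ``kind`` ∈ {tracking, piv, frap, profile}. Returns the in-memory
    objects; if ``out_dir`` is given, also writes them to disk.
    """
    sub = stage_seed(seed, "fixtures")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if kind == "tracking":
        cfg = SimulationConfig(n_particles=12, D=0.05, k_off=0.0, duration=4.9,
                               frame_interval=0.1, long_axis=25.0, short_axis=15.0,
                               spot_amplitude=300.0, background_noise_sd=4.0, seed=sub)
        traj, truth = simulate_trajectories(cfg)
        stack = render_images(traj, cfg)
        result = {"config": cfg, "trajectories": traj, "truth": truth, "stack": stack}
        if out is not None:
            stack.to_tiff(out / "tracking_stack.tif")
            traj.to_csv(out / "tracking_truth.csv")
    elif kind == "piv":
        flow = FlowField.uniform(0.3, -0.15, extent=(20.0, 15.0), spacing=1.0)
        cfg = SimulationConfig(n_particles=0, long_axis=20.0, short_axis=15.0,
                               pixel_size=0.1, frame_interval=1.0, duration=5.0,
                               background_noise_sd=1.0, spot_amplitude=150.0, seed=sub)
        stack = render_cortex_texture(flow, cfg, n_frames=6)
        result = {"stack": stack, "flow_truth": flow,
                  "displacement_px_per_frame": (3.0, -1.5)}
        if out is not None:
            stack.to_tiff(out / "piv_stack.tif")
            flow.to_csv(out / "piv_truth.csv")
    elif kind == "frap":
        from .membrane_quant import synthetic_frap_curve

        curves = {}
        for i, tau in enumerate((50.0, 150.0, 400.0)):
            t, y = synthetic_frap_curve(tau, plateau=0.9, duration=1200.0,
                                        noise_sd=0.02, seed=sub + i)
            curves[tau] = (t, y)
        result = {"curves": curves}
        if out is not None:
            for tau, (t, y) in curves.items():
                pd.DataFrame({"time_s": t, "intensity": y}).to_csv(
                    out / f"frap_tau{int(tau)}.csv", index=False)
    elif kind == "profile":
        from .membrane_quant import synthetic_straightened_image

        pos = np.linspace(0, 1, 120)
        membrane = 100.0 * (1 - 0.8 * (1 + np.tanh((pos - 0.6) * 8)) / 2)
        img = synthetic_straightened_image(membrane, 40.0, noise_sd=2.0, seed=sub)
        result = {"image": img, "membrane_truth": membrane, "cytoplasm_truth": 40.0}
        if out is not None:
            np.savetxt(out / "profile_image.csv", img, delimiter=",")
            np.savetxt(out / "profile_truth.csv", membrane, delimiter=",")
    else:
        raise ValueError(f"unknown fixture kind: {kind}")
    return result
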