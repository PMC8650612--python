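"""Experiment drivers and the disk-based pipeline.

Two layers:

* **In-memory experiments** (``profile_series``, ``run_confined_kinetics``,
  ``run_expansion``, ``run_tracking``, ``run_spontaneous``) chain
  simulate → render → binarize → profile → estimate without touching disk;
  these are the parameter-recovery entry points.
* **Disk stages** (``run_pipeline`` with a :class:`RunConfig`) write every
  intermediate product (TIFF stack, tidy CSVs, JSON summaries, figures)
  into one directory per seed plus an aggregate report, with idempotent
  skip-if-exists semantics.  Every run directory contains the resolved
  configuration, so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import corona_kinetics as ck
from . import density_field as df_
from . import io as io_
from . import track_metrics as tm
from .colony_sim import SimulationResult, simulate
from .density_field import BinaryFrame, RadialBinner, RadialProfile
from .params import ColonyParams, get_preset

__all__ = [
    "RunConfig",
    "ReportSummary",
    "profile_series",
    "run_confined_kinetics",
    "run_expansion",
    "run_tracking",
    "run_spontaneous",
    "run_pipeline",
]

log = logging.getLogger("coronakit")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat, serializable configuration for a full pipeline run."""

    preset: str = "AX2-confined"
    overrides: dict = field(default_factory=dict)
    seeds: List[int] = field(default_factory=lambda: [0])
    out_dir: str = "runs"
    stages: List[str] = field(default_factory=lambda: [
        "simulate", "density", "corona", "tracks", "report"])
    skip_existing: bool = False
    # density stage
    block_size: int = 51
    offset: float = 2.0
    bin_width: float = 30.0
    # corona stage
    smooth_width: int = 5
    peripheral_fraction: float = 0.5
    persistence: int = 3
    vi_window: float = 140.0
    vf_from: float = 600.0
    vf_to: float = 1440.0
    expansion_t_max: float = 300.0
    # tracks stage
    feature_diameter: float = 10.0
    max_speed: float = 10.0
    interval_min: float = 1.0
    speed_floor: float = 0.5
    window_um: float = 150.0
    step_um: float = 25.0
    n_min: int = 300
    track_start: Optional[float] = None     # min; default: mid-run
    track_duration: float = 30.0            # min
    track_fpm: float = 3.0                  # frames per minute

    def params(self, seed: int) -> ColonyParams:
        return get_preset(self.preset, seed=seed, **self.overrides)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ReportSummary:
    per_run: dict                 # seed -> metrics dict
    aggregates: dict              # metric -> {mean, sd, n}

    def to_dict(self) -> dict:
        return {"per_run": self.per_run, "aggregates": self.aggregates}


# ---------------------------------------------------------------------------
# In-memory experiments
# ---------------------------------------------------------------------------

def profile_series(
    sim: SimulationResult,
    block_size: int = 51,
    offset: float = 2.0,
    bin_width: float = 30.0,
) -> List[RadialProfile]:
    """Render → binarize → radial profile for every recorded frame.

    Frames are rendered and consumed one at a time (long runs never hold a
    full stack).  The colony center is the foreground centroid of the first
    frame and is reused for all later times.
    """
    p = sim.params
    binner = None
    profiles = []
    for i in range(len(sim.frame_times)):
        frame = sim.render(i)
        bf = df_.binarize_adaptive(frame, block_size, offset,
                                   pixel_size=p.pixel_size, time=float(sim.frame_times[i]))
        if binner is None:
            center = df_.estimate_center(bf)
            binner = RadialBinner(bf.mask.shape, p.pixel_size, center, bin_width)
        profiles.append(binner.profile(bf))
    return profiles


def run_confined_kinetics(params: ColonyParams, cfg: Optional[RunConfig] = None) -> dict:
    """End-to-end ring kinetics on one confined run (images → T*, v_i, v_f)."""
    cfg = cfg or RunConfig()
    sim = simulate(params)
    profiles = profile_series(sim, cfg.block_size, cfg.offset, cfg.bin_width)
    trace = ck.build_trace(profiles, cfg.smooth_width, cfg.peripheral_fraction)
    summary = ck.kinetics_summary(trace, cfg.vi_window, cfg.vf_from, cfg.vf_to,
                                  cfg.persistence)
    return {"sim": sim, "profiles": profiles, "trace": trace, "summary": summary}


def run_expansion(params: ColonyParams, cfg: Optional[RunConfig] = None) -> ck.ExpansionEstimate:
    """Unconfined border-expansion velocity by the threshold sweep."""
    cfg = cfg or RunConfig()
    sim = simulate(params)
    profiles = profile_series(sim, cfg.block_size, cfg.offset, cfg.bin_width)
    return ck.expansion_velocity(profiles, lapse=params.frame_interval,
                                 t_max=cfg.expansion_t_max)


def _tracking_params(params: ColonyParams, cfg: RunConfig) -> ColonyParams:
    t0 = cfg.track_start
    if t0 is None:
        t0 = min(270.0, max(0.0, params.duration_min - cfg.track_duration))
    t1 = min(t0 + cfg.track_duration, params.duration_min)
    times = tuple(np.round(np.arange(t0, t1 + 1e-9, 1.0 / cfg.track_fpm), 6))
    return params.replace(frame_times=times, duration_h=t1 / 60.0)


def run_tracking(params: ColonyParams, cfg: Optional[RunConfig] = None) -> dict:
    """Single-cell tracking protocol: 30-min window at 3 frames/min.

    Renders the window, detects cells, links them, computes 1-min velocity
    samples and the 150-μm sliding-window directionality profile, plus von
    Mises fits of step headings (relative to the outward radial direction)
    for the corona, intermediate and whole-field populations.
    """
    cfg = cfg or RunConfig()
    tp = _tracking_params(params, cfg)
    sim = simulate(tp)
    min_mass = df_.default_min_mass(tp)
    dets = []
    center = None
    for i in range(len(sim.frame_times)):
        frame = sim.render(i)
        if center is None:
            bf = df_.binarize_adaptive(frame, cfg.block_size, cfg.offset,
                                       pixel_size=tp.pixel_size)
            center = df_.estimate_center(bf)
        d = df_.detect_features(frame, tp.pixel_size, cfg.feature_diameter,
                                min_mass, time=float(sim.frame_times[i]))
        dets.append(d)
    detections = pd.concat(dets, ignore_index=True)
    tracks = tm.link_tracks(detections, cfg.max_speed, cfg.feature_diameter)
    samples = tm.velocity_samples(tracks, center=center, interval=cfg.interval_min,
                                  speed_floor=cfg.speed_floor)
    profile = tm.sliding_window_profile(samples, cfg.window_um, cfg.step_um, cfg.n_min)

    # von Mises fit of step headings relative to outward radial (μ = 0 means
    # radially outward).  cosθ is the directionality ratio; a fixed-μ=0 fit
    # depends on the headings only through mean cosθ, so the sign of the
    # tangential component is immaterial and arccos(ratio) suffices.
    valid = samples[samples["speed"] >= cfg.speed_floor].dropna(subset=["ratio"])
    fits = {}
    if len(valid) >= 5:
        headings = np.arccos(np.clip(valid["ratio"].to_numpy(), -1.0, 1.0))
        fits["all"] = tm.vonmises_fit(headings, fix_mu=0.0)
    ring_r = sim.ring_radius_at(float(np.median(sim.frame_times)))
    return {"sim": sim, "detections": detections, "tracks": tracks,
            "samples": samples, "profile": profile, "center": center,
            "ring_radius": ring_r, "vonmises": fits}


def run_spontaneous(params: ColonyParams, cfg: Optional[RunConfig] = None) -> float:
    """Uniform-field protocol end-to-end: render → detect → link → mean |v|."""
    cfg = cfg or RunConfig()
    sim = simulate(params)
    min_mass = df_.default_min_mass(params)
    dets = []
    for i in range(len(sim.frame_times)):
        d = df_.detect_features(sim.render(i), params.pixel_size,
                                cfg.feature_diameter, min_mass,
                                time=float(sim.frame_times[i]))
        dets.append(d)
    tracks = tm.link_tracks(pd.concat(dets, ignore_index=True), cfg.max_speed)
    return tm.spontaneous_motility(tracks, interval=cfg.interval_min)


# ---------------------------------------------------------------------------
# Disk stages
# ---------------------------------------------------------------------------

def _done(path: Path, skip: bool) -> bool:
    return skip and path.exists()


def _stage_simulate(run_dir: Path, params: ColonyParams, cfg: RunConfig) -> None:
    stack_path = run_dir / "stack.tif"
    if _done(stack_path, cfg.skip_existing):
        log.info("simulate: %s exists, skipped", stack_path)
        return
    t0 = _time.perf_counter()
    sim = simulate(params)
    io_.write_stack(sim.image_stack(), stack_path, params=params)
    io_.write_agents_csv(sim, run_dir / "agents.csv")
    sim.ring_truth.to_csv(run_dir / "ring_truth.csv", index=False)
    if sim.oxygen is not None:
        rows = [pd.DataFrame({"t_min": o.time, "r_um": o.r_grid,
                              "concentration": o.concentration})
                for o in sim.oxygen]
        pd.concat(rows, ignore_index=True).to_csv(run_dir / "oxygen.csv", index=False)
    log.info("simulate: %d frames in %.1f s", len(sim.frame_times),
             _time.perf_counter() - t0)


def _stage_density(run_dir: Path, cfg: RunConfig) -> None:
    out = run_dir / "profiles.csv"
    if _done(out, cfg.skip_existing):
        log.info("density: %s exists, skipped", out)
        return
    stack = io_.read_stack(run_dir / "stack.tif")
    binner = None
    profiles = []
    center = None
    for frame, t in zip(stack.frames, stack.frame_times):
        bf = df_.binarize_adaptive(frame, cfg.block_size, cfg.offset,
                                   pixel_size=stack.pixel_size, time=float(t))
        if binner is None:
            center = df_.estimate_center(bf)
            binner = RadialBinner(bf.mask.shape, stack.pixel_size, center, cfg.bin_width)
        profiles.append(binner.profile(bf))
    io_.write_profiles_csv(profiles, out)
    (run_dir / "center.json").write_text(json.dumps({"x_um": center[0], "y_um": center[1]}))
    _plot_heatmap(profiles, run_dir / "density_heatmap.png")


def _stage_corona(run_dir: Path, cfg: RunConfig) -> None:
    out = run_dir / "kinetics.json"
    if _done(out, cfg.skip_existing):
        log.info("corona: %s exists, skipped", out)
        return
    center = json.loads((run_dir / "center.json").read_text())
    profiles = io_.read_profiles_csv(run_dir / "profiles.csv",
                                     center=(center["x_um"], center["y_um"]))
    trace = ck.build_trace(profiles, cfg.smooth_width, cfg.peripheral_fraction)
    summary = ck.kinetics_summary(trace, cfg.vi_window, cfg.vf_from, cfg.vf_to,
                                  cfg.persistence)
    trace.to_frame().to_csv(run_dir / "trace.csv", index=False)
    payload = summary.to_dict()
    if not summary.ring_absent:
        geom = ck.ring_geometry(profiles, trace)
        geom.binned.to_csv(run_dir / "ring_geometry.csv", index=False)
        _plot_kinetics(trace, summary, run_dir / "displacement.png")
    out.write_text(json.dumps(payload, indent=1))


def _stage_tracks(run_dir: Path, cfg: RunConfig, params: ColonyParams) -> None:
    out = run_dir / "directionality.csv"
    if _done(out, cfg.skip_existing):
        log.info("tracks: %s exists, skipped", out)
        return
    res = run_tracking(params, cfg)
    res["tracks"][["track_id", "t_min", "x_um", "y_um"]].to_csv(
        run_dir / "tracks.csv", index=False)
    res["samples"].to_csv(run_dir / "velocity_samples.csv", index=False)
    res["profile"].to_csv(out, index=False)
    fits = {k: v.to_dict() for k, v in res["vonmises"].items()}
    (run_dir / "vonmises.json").write_text(json.dumps(fits, indent=1))


def _run_metrics(run_dir: Path) -> dict:
    """Collect the per-run scalar metrics written by the stages."""
    m = {}
    kin = run_dir / "kinetics.json"
    if kin.exists():
        m.update(json.loads(kin.read_text()))
    prof = run_dir / "directionality.csv"
    if prof.exists():
        d = pd.read_csv(prof)
        if len(d):
            m["max_directionality"] = float(d["mean_ratio"].max())
            m["mean_speed_um_per_min"] = float(d["mean_speed"].mean())
    return m


def run_pipeline(cfg: RunConfig) -> ReportSummary:
    """Execute the configured stages for every seed and aggregate.

    Each seed gets its own run directory containing the resolved
    configuration.  A stage failure halts its dependents for that seed but
    other seeds continue; failures are logged with the stage name.  The
    aggregate summary (mean ± sd over successful runs, with n) is written
    beside the run directories and always equals a recomputation from the
    per-run JSONs.
    """
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_root / "config.yaml")
    per_run = {}
    for seed in cfg.seeds:
        run_dir = out_root / f"seed-{seed}"
        run_dir.mkdir(exist_ok=True)
        params = cfg.params(seed)
        cfg.to_yaml(run_dir / "config.yaml")
        (run_dir / "params.json").write_text(json.dumps(params.to_dict(), indent=1))
        failed = set()
        for stage in cfg.stages:
            if stage == "report":
                continue
            deps = {"density": {"simulate"}, "corona": {"simulate", "density"},
                    "tracks": {"simulate"}}.get(stage, set())
            if deps & failed:
                log.error("seed %s: stage %s skipped (dependency failed)", seed, stage)
                continue
            try:
                if stage == "simulate":
                    _stage_simulate(run_dir, params, cfg)
                elif stage == "density":
                    _stage_density(run_dir, cfg)
                elif stage == "corona":
                    _stage_corona(run_dir, cfg)
                elif stage == "tracks":
                    _stage_tracks(run_dir, cfg, params)
                else:
                    raise ValueError(f"unknown stage {stage!r}")
            except Exception:
                log.exception("seed %s: stage %s failed", seed, stage)
                failed.add(stage)
        per_run[str(seed)] = _run_metrics(run_dir)

    aggregates = _aggregate(per_run)
    summary = ReportSummary(per_run=per_run, aggregates=aggregates)
    if "report" in cfg.stages:
        (out_root / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
    return summary


def _aggregate(per_run: dict) -> dict:
    keys = set()
    for m in per_run.values():
        keys |= {k for k, v in m.items() if isinstance(v, (int, float)) and v is not None}
    agg = {}
    for k in sorted(keys):
        vals = [m[k] for m in per_run.values()
                if isinstance(m.get(k), (int, float)) and m[k] is not None]
        if vals:
            agg[k] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals)),
                      "n": len(vals)}
    return agg


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _plot_heatmap(profiles: Sequence[RadialProfile], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = np.stack([p.relative_density for p in profiles])
    t = [p.time for p in profiles]
    r = profiles[0].bin_centers
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(r, t, z, shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="relative density (%)")
    ax.set_xlabel("radius (μm)")
    ax.set_ylabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_kinetics(trace: ck.CoronaTrace, summary: ck.KineticsSummary, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t, r = trace.times, trace.r_peak
    ax.plot(t[trace.present], r[trace.present], ".", ms=3, label="detected ring")
    if summary.t_star is not None:
        ts = summary.t_star
        if summary.v_i is not None:
            tt = np.linspace(ts, ts + summary.vi_window, 20)
            i0 = int(np.argmin(np.abs(t - ts)))
            ax.plot(tt, r[i0] + summary.v_i * (tt - ts), "-",
                    label=f"v_i = {summary.v_i:.2f} μm/min")
        if summary.v_f is not None:
            f0, f1 = summary.vf_window
            sel = trace.present & (t >= f0) & (t <= f1)
            if sel.sum() >= 2:
                coef = np.polyfit(t[sel], r[sel], 1)
                tt = np.linspace(f0, f1, 20)
                ax.plot(tt, np.polyval(coef, tt), "-",
                        label=f"v_f = {summary.v_f:.2f} μm/min")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("ring radius (μm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
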