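"""Reference recovery experiments: the study protocols, end to end.

Each function runs one complete synthetic experiment — generate a colony,
render it, push the frames through the measurement pipeline — and returns
the recovered quantity.  These are the canonical protocols used for
parameter-recovery validation; the problem sizes (5,000 agents, 2048-px
frames, 24 h of one-minute steps with an 8-min recording cadence after the
initial phase) are the package's desk-scale study conditions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import corona_kinetics as ck_
from .params import ColonyParams, get_preset
from .pipeline import (
    RunConfig,
    profile_series,
    run_confined_kinetics,
    run_expansion,
    run_spontaneous,
    run_tracking,
)

__all__ = [
    "confined_frame_times",
    "ax2_confined_kinetics",
    "mechanistic_formation_time",
    "nc_expansion_velocity",
    "ring_directionality",
    "nc_directionality_max",
    "spontaneous_speed",
]


def confined_frame_times(duration_min: float = 1440.0, dense_until: float = 240.0,
                         dense_dt: float = 1.0, sparse_dt: float = 8.0) -> tuple:
    """Recording schedule for 24-h confined runs: one frame per minute
    through formation and the initial-speed window, then one frame per
    8 min for the late linear regime (an OLS slope over 10–24 h gains
    nothing from minute sampling)."""
    dense = np.arange(0.0, dense_until, dense_dt)
    sparse = np.arange(dense_until, duration_min + 1e-9, sparse_dt)
    return tuple(np.concatenate([dense, sparse]))


def ax2_confined_kinetics(seed: int, preset: str = "AX2-confined",
                          cfg: Optional[RunConfig] = None) -> ck_.KineticsSummary:
    """Full 24-h confined kinematic run → (T*, v_i, v_f) from images."""
    params = get_preset(preset, seed=seed, frame_times=confined_frame_times())
    cfg = cfg or RunConfig()
    return run_confined_kinetics(params, cfg)["summary"]


def mechanistic_formation_time(seed: int, preset: str = "AX2-confined",
                               duration_h: float = 2.5) -> Optional[float]:
    """Mechanistic-mode run (oxygen-driven, emergent ring) → detected T*.

    Only the onset matters, so the run covers the first ``duration_h``
    hours at one frame per minute.
    """
    params = get_preset(preset, seed=seed, duration_h=duration_h).replace(
        mode="mechanistic")
    return run_confined_kinetics(params)["summary"].t_star


def nc_expansion_velocity(seed: int) -> float:
    """Unconfined 5-h run → border expansion velocity (9-threshold sweep)."""
    return run_expansion(get_preset("NC-spreading", seed=seed)).v_nc


def ring_directionality(seed: int) -> tuple:
    """30-min tracking on a confined run → <v_r/|v|> at the ground-truth
    ring radius.  Returns (value, n samples in that window)."""
    res = run_tracking(get_preset("AX2-confined", seed=seed))
    prof = res["profile"]
    if not len(prof):
        return np.nan, 0
    i = (prof["r_um"] - res["ring_radius"]).abs().idxmin()
    return float(prof.loc[i, "mean_ratio"]), int(prof.loc[i, "n"])


def nc_directionality_max(seed: int) -> tuple:
    """Same tracking protocol on the unconfined control → max over R of the
    sliding-window directionality.  Returns (value, total samples)."""
    res = run_tracking(get_preset("NC-spreading", seed=seed))
    prof = res["profile"]
    if not len(prof):
        return np.nan, 0
    return float(prof["mean_ratio"].max()), int(prof["n"].sum())


def spontaneous_speed(seed: int) -> float:
    """Uniform-field protocol → mean per-minute instantaneous speed."""
    return run_spontaneous(get_preset("uniform-motility", seed=seed))
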