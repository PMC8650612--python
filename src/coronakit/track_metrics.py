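"""Single-cell tracking statistics.

Links per-frame detections into tracks by greedy nearest-neighbor
assignment (no gap closing), computes per-minute instantaneous speed |v|
and the radial velocity component v_r in the colony's polar frame, builds
150-μm sliding-window radial motility profiles <|v|>(R), <v_r>(R) and
<v_r/|v|>(R), fits von Mises distributions to step-heading angles relative
to the outward radial direction (so μ = 0 means radially outward), and
measures spontaneous motility on uniformly scattered cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import i0e, i1e

from .params import KAPPA_CAP, mean_resultant

__all__ = [
    "VonMisesFit",
    "link_tracks",
    "velocity_samples",
    "sliding_window_profile",
    "vonmises_fit",
    "spontaneous_motility",
]


@dataclass
class VonMisesFit:
    """Maximum-likelihood von Mises parameters for a heading sample."""

    mu: float                 # rad, in (−π, π]
    kappa: float              # ≥ 0, capped
    n: int
    log_likelihood: float
    mu_fixed: bool = False
    at_cap: bool = False      # all angles identical → κ pinned at the cap

    def to_dict(self) -> dict:
        return {"mu_rad": self.mu, "kappa": self.kappa, "n": self.n,
                "log_likelihood": self.log_likelihood,
                "mu_fixed": self.mu_fixed, "kappa_at_cap": self.at_cap}


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_tracks(
    detections: pd.DataFrame,
    max_speed: float = 10.0,
    feature_diameter: float = 10.0,
) -> pd.DataFrame:
    """Link detections across frames into tracks (greedy nearest neighbor).

    Candidate links between consecutive frames are all pairs within the
    search radius ``max_speed × Δt``; they are accepted in order of global
    distance (deterministic conflict resolution), each detection linking at
    most once.  Unmatched detections start new tracks; there is no gap
    closing, so a missed detection terminates its track.

    ``detections`` needs columns t_min, x_um, y_um; the result adds a
    ``track_id`` column.  No produced track ever violates the per-interval
    displacement bound max_speed × Δt.
    """
    if not len(detections):
        return detections.assign(track_id=pd.Series(dtype=np.int64))
    det = detections.sort_values("t_min", kind="stable").reset_index(drop=True)
    times = np.sort(det["t_min"].unique())
    if len(times) < 2:
        raise ValueError("need detections in at least 2 frames to link")
    track_id = np.full(len(det), -1, dtype=np.int64)
    frame_idx = {t: np.flatnonzero(det["t_min"].to_numpy() == t) for t in times}
    next_track = 0
    first = frame_idx[times[0]]
    track_id[first] = np.arange(len(first))
    next_track = len(first)

    xy = det[["x_um", "y_um"]].to_numpy()
    for t_prev, t_next in zip(times[:-1], times[1:]):
        ip = frame_idx[t_prev]
        inx = frame_idx[t_next]
        radius = max_speed * (t_next - t_prev)
        tree = cKDTree(xy[inx])
        pairs = []
        for a, p in enumerate(ip):
            for b in tree.query_ball_point(xy[p], radius):
                d = np.hypot(*(xy[inx[b]] - xy[p]))
                pairs.append((d, a, b))
        pairs.sort()
        used_prev = np.zeros(len(ip), dtype=bool)
        used_next = np.zeros(len(inx), dtype=bool)
        for d, a, b in pairs:
            if used_prev[a] or used_next[b]:
                continue
            used_prev[a] = used_next[b] = True
            track_id[inx[b]] = track_id[ip[a]]
        for b in np.flatnonzero(~used_next):
            track_id[inx[b]] = next_track
            next_track += 1
    det["track_id"] = track_id
    return det


# ---------------------------------------------------------------------------
# Velocity samples
# ---------------------------------------------------------------------------

def velocity_samples(
    tracks: pd.DataFrame,
    center: Tuple[float, float] = (0.0, 0.0),
    interval: float = 1.0,
    speed_floor: float = 0.5,
    time_tol: float = 1e-4,
    origin: Optional[float] = None,
) -> pd.DataFrame:
    """Per-interval speed and radial velocity for every track.

    Speeds are measured over *disjoint* periods of ``interval`` minutes
    aligned to a common grid (anchored at ``origin``, by default the
    earliest time in the table), so movies recorded at a higher frame rate
    contribute one sample per cell per interval — the in-between frames
    serve linking, not velocimetry.  For each position pair: |v| = ‖Δx‖/Δt
    and v_r = (Δx · r̂)/Δt with r̂ the outward unit vector from ``center``
    at the interval start.  |v_r| ≤ |v| always.  The directionality ratio
    v_r/|v| is NaN (excluded from averages) when |v| < ``speed_floor`` —
    the direction of a near-zero step is noise.

    Returns a tidy frame: track_id, t_min, r_um, speed, v_r, ratio.
    """
    col = "track_id" if "track_id" in tracks.columns else "id"
    out = []
    cx, cy = center
    if origin is None and len(tracks):
        origin = float(tracks["t_min"].min())
    for tid, g in tracks.groupby(col, sort=True):
        g = g.sort_values("t_min")
        t = g["t_min"].to_numpy(dtype=float)
        x = g["x_um"].to_numpy(dtype=float)
        y = g["y_um"].to_numpy(dtype=float)
        if len(t) < 2:
            continue
        # match indices separated by `interval`
        j = np.searchsorted(t, t + interval - time_tol)
        j = np.clip(j, 0, len(t) - 1)
        ok = np.abs(t[j] - (t + interval)) <= time_tol
        # keep only interval starts on the common grid
        phase = np.abs((t - origin) / interval - np.round((t - origin) / interval))
        ok &= phase * interval <= time_tol
        i = np.flatnonzero(ok)
        if len(i) == 0:
            continue
        jj = j[i]
        dx = x[jj] - x[i]
        dy = y[jj] - y[i]
        dt = t[jj] - t[i]
        speed = np.hypot(dx, dy) / dt
        rx, ry = x[i] - cx, y[i] - cy
        rr = np.hypot(rx, ry)
        with np.errstate(invalid="ignore", divide="ignore"):
            v_r = np.where(rr > 0, (dx * rx + dy * ry) / rr / dt, 0.0)
            ratio = np.where(speed >= speed_floor, v_r / speed, np.nan)
        out.append(pd.DataFrame({
            "track_id": tid, "t_min": t[i], "r_um": rr,
            "speed": speed, "v_r": v_r, "ratio": ratio,
        }))
    if not out:
        return pd.DataFrame(columns=["track_id", "t_min", "r_um", "speed", "v_r", "ratio"])
    return pd.concat(out, ignore_index=True)


def sliding_window_profile(
    samples: pd.DataFrame,
    window: float = 150.0,
    step: float = 25.0,
    n_min: int = 300,
) -> pd.DataFrame:
    """Radial motility profile by the sliding-window method.

    For each grid radius R, averages |v|, v_r and v_r/|v| over samples with
    radius in [R − window/2, R + window/2).  Windows with fewer than
    ``n_min`` samples are dropped (a handful of signed cosines is not a
    directionality estimate).  Returns r_um, mean_speed, mean_vr,
    mean_ratio, n.
    """
    if not len(samples):
        raise ValueError("no velocity samples")
    r = samples["r_um"].to_numpy()
    grid = np.arange(0.0, r.max() + step, step)
    rows = []
    for R in grid:
        sel = (r >= R - window / 2) & (r < R + window / 2)
        n = int(sel.sum())
        if n < n_min:
            continue
        sub = samples[sel]
        rows.append({
            "r_um": float(R),
            "mean_speed": float(sub["speed"].mean()),
            "mean_vr": float(sub["v_r"].mean()),
            "mean_ratio": float(sub["ratio"].mean(skipna=True)),
            "n": n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# von Mises fitting
# ---------------------------------------------------------------------------

def _log_i0(kappa: float) -> float:
    return float(np.log(i0e(kappa)) + kappa)


def _solve_kappa(target: float, tol: float = 1e-8) -> float:
    """Solve A(κ) = I₁(κ)/I₀(κ) = target by bracketed bisection on [0, cap]."""
    if target <= 0:
        return 0.0
    if target >= mean_resultant(KAPPA_CAP):
        return KAPPA_CAP
    lo, hi = 0.0, KAPPA_CAP
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_resultant(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def vonmises_fit(angles: Sequence[float], fix_mu: Optional[float] = None) -> VonMisesFit:
    """Maximum-likelihood von Mises fit f(θ) = exp(κ cos(θ−μ))/(2π I₀(κ)).

    Free μ: μ̂ is the circular mean and κ̂ solves A(κ̂) = R̄ (mean resultant
    length).  Fixed μ: κ̂ solves A(κ̂) = mean cos(θ−μ) when that is positive,
    else κ̂ = 0 (the likelihood is maximized at the uniform boundary).
    κ is capped; a degenerate sample of identical angles pins κ̂ at the cap
    and sets ``at_cap``.  Requires n ≥ 5.
    """
    th = np.asarray(angles, dtype=float)
    n = len(th)
    if n < 5:
        raise ValueError("need at least 5 angles for a von Mises fit")
    c, s = np.cos(th), np.sin(th)
    if fix_mu is None:
        mu = float(np.arctan2(s.mean(), c.mean()))
        r_bar = float(np.hypot(c.mean(), s.mean()))
        target = r_bar
        mu_fixed = False
    else:
        mu = float((fix_mu + np.pi) % (2 * np.pi) - np.pi)
        target = float(np.cos(th - mu).mean())
        mu_fixed = True
    at_cap = target >= mean_resultant(KAPPA_CAP)
    kappa = _solve_kappa(target)
    mean_cos = float(np.cos(th - mu).mean())
    ll = n * (kappa * mean_cos - np.log(2 * np.pi) - _log_i0(kappa))
    return VonMisesFit(mu=mu, kappa=kappa, n=n, log_likelihood=float(ll),
                       mu_fixed=mu_fixed, at_cap=bool(at_cap))


# ---------------------------------------------------------------------------
# Spontaneous motility
# ---------------------------------------------------------------------------

def spontaneous_motility(
    tracks: pd.DataFrame,
    interval: float = 1.0,
) -> float:
    """Mean per-interval instantaneous speed over all tracks (μm/min).

    The uniform-field protocol: cells scattered over the plate with no
    oxygen gradient; the mean |v| over 1-min intervals is the spontaneous
    (random) motility.
    """
    samples = velocity_samples(tracks, center=(0.0, 0.0), interval=interval,
                               speed_floor=0.0)
    if not len(samples):
        raise ValueError("no velocity samples in the provided tracks")
    return float(samples["speed"].mean())
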