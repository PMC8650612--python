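"""Ring (*corona*) detection and kinetics from radial-profile series.

Given radial density profiles over time this module finds the peripheral
density peak that marks the migrating ring, estimates its formation time
T* (first persistent detection), its initial propagation speed v_i (mean
per-interval velocity in a window after formation, default 140 min), its
late constant speed v_f (ordinary least-squares slope of R(t) over the
10–24 h window), ring width/density dynamics with the area-conservation
prediction L(t) = L0·R0/R(t), the expansion velocity of unconfined
colonies by a threshold sweep on the border radius, and a duplication
ratio from cell counts in a fixed circular sector (by symmetry there is no
net flux through a sector, so count changes can only come from division).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .density_field import RadialProfile

__all__ = [
    "CoronaTrace",
    "KineticsSummary",
    "RingModelPrediction",
    "RingGeometry",
    "ExpansionEstimate",
    "DuplicationSeries",
    "detect_corona",
    "build_trace",
    "formation_time",
    "initial_speed",
    "late_speed",
    "ring_geometry",
    "ring_width_model",
    "expansion_velocity",
    "duplication_estimate",
    "colony_radius_from_profile",
    "kinetics_summary",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CoronaTrace:
    """Time series of detected ring radius; absence is a value, not an error."""

    times: np.ndarray          # min
    r_peak: np.ndarray         # μm, NaN where absent
    present: np.ndarray        # bool
    colony_radius: float = np.nan

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.r_peak = np.asarray(self.r_peak, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)

    def displacement(self, t_star: float) -> np.ndarray:
        """ΔR(t) = R(t) − R(T*); zero at T* by construction."""
        i0 = int(np.argmin(np.abs(self.times - t_star)))
        return self.r_peak - self.r_peak[i0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.times, "r_peak_um": self.r_peak,
                             "present": self.present})


@dataclass
class KineticsSummary:
    t_star: Optional[float]            # min; None if the ring never persists
    v_i: Optional[float]               # μm/min
    v_f: Optional[float]               # μm/min
    latency_bound: float = 0.0         # min, persistence × frame interval
    vi_window: float = 140.0
    vf_window: Tuple[float, float] = (600.0, 1440.0)
    vf_residual_sd: Optional[float] = None
    ring_absent: bool = False

    def to_dict(self) -> dict:
        return {
            "t_star_min": self.t_star,
            "v_i_um_per_min": self.v_i,
            "v_f_um_per_min": self.v_f,
            "latency_bound_min": self.latency_bound,
            "vi_window_min": self.vi_window,
            "vf_window_min": list(self.vf_window),
            "vf_residual_sd_um": self.vf_residual_sd,
            "ring_absent": self.ring_absent,
        }


@dataclass
class RingModelPrediction:
    """Area-conservation prediction for a ring of constant density."""

    r: np.ndarray             # μm
    width: np.ndarray         # μm
    conserved_product: float  # R·L, μm²


@dataclass
class RingGeometry:
    times: np.ndarray
    width: np.ndarray          # μm, 0 where flagged
    density: np.ndarray        # %, mean over the ring extent
    flagged: np.ndarray        # floor above the peak at that time
    binned: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ExpansionEstimate:
    v_nc: float                      # μm/min, mean over thresholds
    per_threshold: dict              # threshold (%) -> mean velocity
    thresholds: np.ndarray           # % values used


@dataclass
class DuplicationSeries:
    times: np.ndarray
    counts: np.ndarray
    ratio: np.ndarray
    reference_time: float


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _smooth(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return v.astype(float)
    k = np.ones(width) / width
    # reflect-pad so the ends are not biased toward zero
    pad = width // 2
    vp = np.concatenate([v[pad:0:-1], v, v[-2:-2 - pad:-1]])
    return np.convolve(vp, k, mode="valid")


def colony_radius_from_profile(profile: RadialProfile, floor_frac: float = 0.02) -> float:
    """Outermost radius where density still reaches ``floor_frac`` of the
    profile maximum — the colony extent at that time.  The floor sits well
    below the density of the colony rim but well above the binarization
    noise of empty annuli, so the estimate does not flicker with the seed."""
    v = profile.relative_density
    if v.max() <= 0:
        return np.nan
    above = np.nonzero(v >= floor_frac * v.max())[0]
    return float(profile.bin_centers[above[-1]]) if len(above) else np.nan


def _noise_floor(values: np.ndarray, n_tail: int = 10, min_prominence: float = 0.5) -> float:
    """Prominence floor: 2 × sd of bin-to-bin differences in the outermost
    annuli (assumed empty of cells; frame corners at minimum), but never
    below ``min_prominence`` — a colony of finitely many cells carries
    Poisson texture in its interior annuli that the empty-edge estimate
    cannot see, and texture bumps reach prominences of a few tenths of a
    percent."""
    tail = values[-min(n_tail, max(len(values) // 4, 2)):]
    sd = float(np.std(np.diff(tail))) if len(tail) >= 3 else 0.0
    return max(2.0 * sd, min_prominence)


def detect_corona(
    profile: RadialProfile,
    smooth_width: int = 5,
    peripheral_fraction: float = 0.5,
    colony_radius: Optional[float] = None,
    min_prominence: float = 0.5,
) -> Optional[float]:
    """Radius of the outermost peripheral local maximum, or None.

    The profile is moving-average smoothed over ``smooth_width`` bins; a
    candidate peak must lie beyond ``peripheral_fraction`` × colony radius
    and its prominence must exceed the noise floor (empty-annulus estimate
    with the ``min_prominence`` absolute floor).  The returned radius is
    refined to sub-bin precision by parabolic interpolation through the
    peak bin and its neighbors.
    """
    v = np.asarray(profile.relative_density, dtype=float)
    if len(v) < 5:
        raise ValueError("profile must have at least 5 bins")
    if colony_radius is None:
        colony_radius = colony_radius_from_profile(profile)
    if not np.isfinite(colony_radius):
        return None
    s = _smooth(v, smooth_width)
    floor = _noise_floor(v, min_prominence=min_prominence)
    peaks, props = find_peaks(s, prominence=floor)
    if len(peaks) == 0:
        return None
    r = profile.bin_centers
    peripheral = peaks[r[peaks] > peripheral_fraction * colony_radius]
    if len(peripheral) == 0:
        return None
    i = int(peripheral[-1])  # outermost qualifying maximum
    # parabolic refinement
    if 0 < i < len(s) - 1:
        denom = s[i - 1] - 2 * s[i] + s[i + 1]
        delta = 0.5 * (s[i - 1] - s[i + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(r[i] + delta * profile.bin_width)


def build_trace(
    profiles: Sequence[RadialProfile],
    smooth_width: int = 5,
    peripheral_fraction: float = 0.5,
    colony_radius: Optional[float] = None,
    min_prominence: float = 0.5,
) -> CoronaTrace:
    """Run ring detection over a profile series.

    The colony radius defaults to the extent measured on the first profile,
    so the peripheral gate does not drift as the colony rearranges.
    """
    if len(profiles) == 0:
        raise ValueError("empty profile series")
    if colony_radius is None:
        colony_radius = colony_radius_from_profile(profiles[0])
    times = np.array([p.time for p in profiles], dtype=float)
    r_peak = np.full(len(profiles), np.nan)
    for k, p in enumerate(profiles):
        rp = detect_corona(p, smooth_width, peripheral_fraction, colony_radius,
                           min_prominence)
        if rp is not None:
            r_peak[k] = rp
    return CoronaTrace(times=times, r_peak=r_peak, present=np.isfinite(r_peak),
                       colony_radius=colony_radius)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def formation_time(trace: CoronaTrace, persistence: int = 3) -> Optional[float]:
    """Earliest time with ``persistence`` consecutive detections, measured
    from confinement start.  None if the ring is never persistent."""
    present = trace.present
    run = 0
    for k, p in enumerate(present):
        run = run + 1 if p else 0
        if run >= persistence:
            return float(trace.times[k - persistence + 1])
    return None


def initial_speed(trace: CoronaTrace, window: float = 140.0,
                  t_star: Optional[float] = None, persistence: int = 3) -> float:
    """Mean per-interval ring velocity within [T*, T* + window] (μm/min).

    For uniformly sampled traces this equals ΔR over the realized span
    divided by that span.  Requires at least two detections in the window.
    """
    if t_star is None:
        t_star = formation_time(trace, persistence)
    if t_star is None:
        raise ValueError("ring never forms persistently; no initial speed")
    sel = trace.present & (trace.times >= t_star - 1e-9) & (trace.times <= t_star + window + 1e-9)
    t = trace.times[sel]
    r = trace.r_peak[sel]
    if len(t) < 2:
        raise ValueError("fewer than 2 detections inside the initial-speed window")
    v = np.diff(r) / np.diff(t)
    return float(np.mean(v))


def late_speed(trace: CoronaTrace, t_from: float = 600.0, t_to: float = 1440.0) -> float:
    """OLS slope of R(t) on [t_from, t_to] (μm/min); needs ≥5 detections."""
    sel = trace.present & (trace.times >= t_from) & (trace.times <= t_to)
    t = trace.times[sel]
    r = trace.r_peak[sel]
    if len(t) < 5:
        raise ValueError("fewer than 5 detections inside the late-speed window")
    slope, _ = np.polyfit(t, r, 1)
    return float(slope)


def _late_residual_sd(trace: CoronaTrace, t_from: float, t_to: float) -> Optional[float]:
    sel = trace.present & (trace.times >= t_from) & (trace.times <= t_to)
    t, r = trace.times[sel], trace.r_peak[sel]
    if len(t) < 5:
        return None
    coef = np.polyfit(t, r, 1)
    res = r - np.polyval(coef, t)
    return float(np.std(res, ddof=2))


def kinetics_summary(
    trace: CoronaTrace,
    vi_window: float = 140.0,
    vf_from: float = 600.0,
    vf_to: float = 1440.0,
    persistence: int = 3,
) -> KineticsSummary:
    """T*, v_i and v_f for one run, with the detection-latency bound
    (persistence × frame interval) reported alongside T*."""
    dt = float(np.median(np.diff(trace.times))) if len(trace.times) > 1 else 0.0
    t_star = formation_time(trace, persistence)
    if t_star is None:
        return KineticsSummary(t_star=None, v_i=None, v_f=None, ring_absent=True,
                               latency_bound=persistence * dt,
                               vi_window=vi_window, vf_window=(vf_from, vf_to))
    try:
        v_i = initial_speed(trace, vi_window, t_star=t_star)
    except ValueError:
        v_i = None
    try:
        v_f = late_speed(trace, vf_from, vf_to)
    except ValueError:
        v_f = None
    return KineticsSummary(
        t_star=t_star, v_i=v_i, v_f=v_f,
        latency_bound=persistence * dt, vi_window=vi_window,
        vf_window=(vf_from, vf_to),
        vf_residual_sd=_late_residual_sd(trace, vf_from, vf_to),
    )


# ---------------------------------------------------------------------------
# Ring geometry and the area-conservation model
# ---------------------------------------------------------------------------

def _ring_extent(profile: RadialProfile, r_peak: float,
                 density_floor: Optional[float]) -> Tuple[float, float, bool]:
    """(width, mean density, flagged) of the contiguous interval around the
    peak with density ≥ floor.  Edges are located by linear interpolation
    between bin centers.  If the floor exceeds the peak value the width is
    0 and the point is flagged."""
    v = profile.relative_density
    r = profile.bin_centers
    i_peak = int(np.argmin(np.abs(r - r_peak)))
    peak_val = v[i_peak]
    if density_floor is None:
        # 50% of the peak height above the local baseline (minima flanking the ring)
        lo = max(0, i_peak - 10)
        hi = min(len(v), i_peak + 11)
        left_base = v[lo:i_peak].min() if i_peak > lo else 0.0
        right_base = v[i_peak + 1:hi].min() if i_peak + 1 < hi else 0.0
        base = 0.5 * (left_base + right_base)
        floor = base + 0.5 * (peak_val - base)
    else:
        floor = density_floor
    if floor > peak_val:
        return 0.0, 0.0, True
    # walk outwards from the peak while >= floor
    i_lo = i_peak
    while i_lo > 0 and v[i_lo - 1] >= floor:
        i_lo -= 1
    i_hi = i_peak
    while i_hi < len(v) - 1 and v[i_hi + 1] >= floor:
        i_hi += 1
    # sub-bin edge interpolation
    if i_lo > 0 and v[i_lo] != v[i_lo - 1]:
        left = r[i_lo - 1] + (floor - v[i_lo - 1]) / (v[i_lo] - v[i_lo - 1]) * profile.bin_width
    else:
        left = r[i_lo] - profile.bin_width / 2
    if i_hi < len(v) - 1 and v[i_hi] != v[i_hi + 1]:
        right = r[i_hi] + (v[i_hi] - floor) / (v[i_hi] - v[i_hi + 1]) * profile.bin_width
    else:
        right = r[i_hi] + profile.bin_width / 2
    width = max(right - left, 0.0)
    density = float(v[i_lo:i_hi + 1].mean())
    return float(width), density, False


def ring_geometry(
    profiles: Sequence[RadialProfile],
    trace: CoronaTrace,
    density_floor: Optional[float] = None,
    cadence: float = 6.0,
    bin_size: int = 5,
) -> RingGeometry:
    """Ring width L(t) and mean ring density over time.

    The extent at each time is the contiguous radial interval around the
    detected peak with density ≥ floor (absolute %, or by default half the
    peak height above the flanking baseline).  The series is resampled to
    the measurement cadence (default one point per 6 min) and binned
    ``bin_size`` measurements per reported point (mean ± sd).
    """
    times, widths, dens, flags = [], [], [], []
    for p, ok, rp in zip(profiles, trace.present, trace.r_peak):
        if not ok:
            continue
        w, d, flagged = _ring_extent(p, rp, density_floor)
        times.append(p.time)
        widths.append(w)
        dens.append(d)
        flags.append(flagged)
    times = np.asarray(times)
    widths = np.asarray(widths)
    dens = np.asarray(dens)
    flags = np.asarray(flags, dtype=bool)
    binned = pd.DataFrame()
    if len(times) >= 2:
        grid = np.arange(times[0], times[-1] + 1e-9, cadence)
        wi = np.interp(grid, times, widths)
        di = np.interp(grid, times, dens)
        n_groups = len(grid) // bin_size
        rows = []
        for g in range(n_groups):
            sl = slice(g * bin_size, (g + 1) * bin_size)
            rows.append({
                "t_min": float(np.mean(grid[sl])),
                "width_mean_um": float(np.mean(wi[sl])),
                "width_sd_um": float(np.std(wi[sl])),
                "density_mean_pct": float(np.mean(di[sl])),
                "density_sd_pct": float(np.std(di[sl])),
            })
        binned = pd.DataFrame(rows)
    return RingGeometry(times=times, width=widths, density=dens, flagged=flags, binned=binned)


def ring_width_model(L0: float, R0: float, r_t: np.ndarray) -> RingModelPrediction:
    """Constant-density, conserved-cohort ring: L(t) = L0·R0/R(t).

    The product R·L is conserved (R doubling halves L); stepping the
    recursion L(t+Δ) = L(t)·R(t)/R(t+Δ) in any number of stages gives the
    same result as the direct formula.
    """
    r_t = np.asarray(r_t, dtype=float)
    if L0 < 0 or R0 <= 0 or np.any(r_t <= 0):
        raise ValueError("radii must be positive and width non-negative")
    width = L0 * R0 / r_t
    return RingModelPrediction(r=r_t, width=width, conserved_product=float(L0 * R0))


# ---------------------------------------------------------------------------
# Unconfined expansion
# ---------------------------------------------------------------------------

def _border_radius(profile: RadialProfile, threshold: float) -> float:
    """Outermost radius with density ≥ threshold, sub-bin interpolated.
    NaN if the threshold is never attained."""
    v = profile.relative_density
    r = profile.bin_centers
    above = np.nonzero(v >= threshold)[0]
    if len(above) == 0:
        return np.nan
    i = above[-1]
    if i == len(v) - 1 or v[i] == v[i + 1]:
        return float(r[i])
    # interpolate the downward crossing toward the next bin
    return float(r[i] + (v[i] - threshold) / (v[i] - v[i + 1]) * profile.bin_width)


def central_density(profile: RadialProfile, frac_radius: float = 0.25,
                    colony_radius: Optional[float] = None) -> float:
    """Mean relative density within the central part of the colony."""
    if colony_radius is None:
        colony_radius = colony_radius_from_profile(profile)
    sel = profile.bin_centers <= frac_radius * colony_radius
    if not np.any(sel):
        sel = slice(0, 1)
    return float(profile.relative_density[sel].mean())


def expansion_velocity(
    profiles: Sequence[RadialProfile],
    thresholds: Optional[Sequence[float]] = None,
    lapse: float = 1.0,
    t_max: float = 300.0,
) -> ExpansionEstimate:
    """Border-displacement expansion velocity of an unconfined colony.

    For each density threshold the colony border is the outermost radius
    still at that density; per-lapse border velocities are averaged over
    the analysis window (default the first 5 h), then over thresholds.
    The default sweep is 9 thresholds, 10%–50% of the t=0 central density
    in steps of 5%.  Thresholds never attained are dropped with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles per lapse")
    if thresholds is None:
        c0 = central_density(profiles[0])
        thresholds = c0 * np.arange(0.10, 0.501, 0.05)
    thresholds = np.asarray(list(thresholds), dtype=float)
    times = np.array([p.time for p in profiles])
    sel = times <= t_max + 1e-9
    profs = [p for p, s in zip(profiles, sel) if s]
    times = times[sel]
    per_th = {}
    for th in thresholds:
        borders = np.array([_border_radius(p, th) for p in profs])
        ok = np.isfinite(borders)
        if ok.sum() < 2:
            warnings.warn(f"threshold {th:.2f}% never attained; dropped")
            continue
        t_ok, b_ok = times[ok], borders[ok]
        # per-lapse instantaneous velocities, averaged over the window
        v = np.diff(b_ok) / np.diff(t_ok)
        per_th[float(th)] = float(np.mean(v))
    if not per_th:
        raise ValueError("no threshold was ever attained")
    v_nc = float(np.mean(list(per_th.values())))
    return ExpansionEstimate(v_nc=v_nc, per_threshold=per_th,
                             thresholds=np.array(sorted(per_th)))


# ---------------------------------------------------------------------------
# Duplication in a fixed sector
# ---------------------------------------------------------------------------

def duplication_estimate(
    detections: pd.DataFrame,
    sector: Tuple[float, float, float, float],
    reference_time: float = 600.0,
) -> DuplicationSeries:
    """Cell-count ratio N(t)/N0 in a fixed circular sector.

    ``sector`` is (angle_min, angle_max, r_min, r_max) in radians/μm about
    the colony center; ``detections`` is a tidy table (t_min, x_um, y_um).
    N0 is the count at the frame nearest ``reference_time``.  By the
    circular symmetry of the colony there is no net flux through a fixed
    sector, so the ratio isolates duplication.
    """
    a0, a1, r0, r1 = sector
    t = detections["t_min"].to_numpy()
    ang = np.arctan2(detections["y_um"].to_numpy(), detections["x_um"].to_numpy())
    rad = np.hypot(detections["x_um"].to_numpy(), detections["y_um"].to_numpy())
    two_pi = 2 * np.pi
    span = (a1 - a0) % two_pi or two_pi
    in_angle = ((ang - a0) % two_pi) <= span
    in_sector = in_angle & (rad >= r0) & (rad < r1)
    times = np.unique(t)
    counts = np.array([int(np.sum(in_sector & (t == tt))) for tt in times])
    i_ref = int(np.argmin(np.abs(times - reference_time)))
    if counts[i_ref] == 0:
        raise ValueError("sector contains no cells at the reference time")
    ratio = counts / counts[i_ref]
    return DuplicationSeries(times=times, counts=counts, ratio=ratio,
                             reference_time=float(times[i_ref]))
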