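"""Agent-based synthetic colony simulator with ground truth.

Generates confined/unconfined colony time-lapses as bright-field-like image
stacks together with the exact agent trajectories, so every estimator in the
analysis pipeline can be validated by parameter recovery.

Two ways of producing the ring (*corona*):

* **kinematic** — the ring trajectory R(t) is prescribed (piecewise linear:
  formation time, initial speed, crossover, late speed).  At formation a
  conserved cohort — every non-rounded agent beyond ``ring_start_radius −
  corona_band`` (the corona is the colony's outermost structure) — switches
  to the corona state and performs a biased random walk whose mean radial
  drift equals the prescribed ring speed.
* **mechanistic** — a radial oxygen field evolves by explicit
  diffusion–consumption; agents round up below ``c_round`` and switch to
  outward-biased migration when the local concentration falls below
  ``c_crit`` while a gradient is present, so the ring and its formation
  time are emergent.

Motility states: *rounded* agents do not move; *elongated* agents step at
``base_speed`` with von Mises(outward, ``intermediate_kappa``) headings
(κ=0 is the uniform circle, i.e. an unbiased random walk); *corona* agents
step at the state speed with von Mises(outward, ``ring_kappa``) headings.
At the κ cap the sampler degenerates to the exact mean direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional
import warnings

import numpy as np
import pandas as pd

from .params import (
    KAPPA_CAP,
    STATE_CORONA,
    STATE_ELONGATED,
    STATE_ROUNDED,
    STATE_NAMES,
    ColonyParams,
    mean_resultant,
)

__all__ = [
    "OxygenField",
    "ImageStack",
    "SimulationResult",
    "make_colony",
    "step_agents",
    "step_oxygen",
    "render_frame",
    "simulate",
]

AGENT_COLUMNS = ["id", "t_min", "x_um", "y_um", "state", "alive"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class OxygenField:
    """Radial oxygen concentration profile at one time point.

    ``concentration`` is the fraction of air saturation in [0, 1] on a
    uniform, strictly increasing radial grid (μm); the outermost node is a
    fixed oxygenated boundary at 1.0.
    """

    r_grid: np.ndarray
    concentration: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.r_grid.ndim != 1 or len(self.r_grid) < 3:
            raise ValueError("r_grid must be 1-D with at least 3 nodes")
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if self.concentration.shape != self.r_grid.shape:
            raise ValueError("concentration and r_grid shapes differ")
        if np.any(self.concentration < -1e-12) or np.any(self.concentration > 1 + 1e-12):
            raise ValueError("concentration must lie in [0, 1]")

    def at(self, r) -> np.ndarray:
        """Linear interpolation of C at radius r (clamped to the grid)."""
        return np.interp(np.asarray(r, dtype=float), self.r_grid, self.concentration)

    def gradient_at(self, r) -> np.ndarray:
        """dC/dr at radius r by interpolating the finite-difference gradient."""
        g = np.gradient(self.concentration, self.r_grid)
        return np.interp(np.asarray(r, dtype=float), self.r_grid, g)


@dataclass
class ImageStack:
    """Time-ordered grayscale frames with physical calibration."""

    frames: np.ndarray           # (T, H, W) uint8
    pixel_size: float            # μm/px
    frame_times: np.ndarray      # min, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValueError("frame_times length must match number of frames")
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Initial placement
# ---------------------------------------------------------------------------

def make_colony(params: ColonyParams, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Place the initial agents and return the t=0 agent table.

    Confined/unconfined colonies use a truncated half-Gaussian radial law
    (sd = 0.6 × drop_radius, truncated at the drop radius) with uniform
    angles, which makes the expected areal density decrease monotonically
    from the center — the arrangement seen at seeding.  ``uniform`` mode
    scatters agents over the whole field of view instead.

    Deterministic given the seed in ``params`` (or the supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 0])
    n = params.n_cells
    if params.mode == "uniform":
        h = params.half_width
        x = rng.uniform(-h, h, size=n)
        y = rng.uniform(-h, h, size=n)
        state = np.full(n, STATE_ELONGATED, dtype=np.int8)
    else:
        if params.drop_radius == 0:
            r = np.zeros(n)
        else:
            sd = 0.6 * params.drop_radius
            # half-Gaussian truncated at the drop radius, via inverse CDF
            from scipy.stats import halfnorm
            u = rng.uniform(0, 1, size=n)
            cmax = halfnorm.cdf(params.drop_radius, scale=sd)
            r = halfnorm.ppf(u * cmax, scale=sd)
        theta = rng.uniform(0, 2 * np.pi, size=n)
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        state = np.where(r < params.core_radius, STATE_ROUNDED, STATE_ELONGATED).astype(np.int8)
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "t_min": 0.0,
            "x_um": x,
            "y_um": y,
            "state": state,
            "alive": True,
        }
    )


# ---------------------------------------------------------------------------
# Oxygen dynamics
# ---------------------------------------------------------------------------

def max_stable_dt(dr: float, diffusion: float) -> float:
    """Stability bound of the explicit radial scheme: dt ≤ Δr²/(4D)."""
    if diffusion <= 0:
        return np.inf
    return dr * dr / (4.0 * diffusion)


def step_oxygen(
    oxy: OxygenField,
    density: np.ndarray,
    dt: float,
    diffusion: float,
    consumption: float,
    km: float = 0.05,
) -> OxygenField:
    """One explicit update of radial diffusion + density-scaled consumption.

    dC/dt = D (C'' + C'/r) − k ρ(r) C/(C+Km), with a symmetric node at r=0
    and the outermost node pinned at 1.0 (oxygenated edge).  ``density`` is
    the relative cell density evaluated on ``oxy.r_grid`` (dimensionless,
    ~1 in the colony core).  Values are clipped to [0, 1].

    Raises ``ValueError`` if ``dt`` violates the explicit stability bound,
    naming the maximum admissible step.
    """
    r = oxy.r_grid
    dr = float(r[1] - r[0])
    dt_max = max_stable_dt(dr, diffusion)
    if dt > dt_max * (1 + 1e-12):
        raise ValueError(
            f"dt={dt:g} min violates the explicit stability bound; "
            f"max admissible dt is {dt_max:g} min for dr={dr:g} μm, D={diffusion:g} μm²/min"
        )
    c = oxy.concentration
    rho = np.asarray(density, dtype=float)
    if rho.shape != c.shape:
        raise ValueError("density must be evaluated on the oxygen grid")
    lap = np.zeros_like(c)
    # interior nodes: C'' + C'/r
    lap[1:-1] = (c[2:] - 2 * c[1:-1] + c[:-2]) / dr**2 + (c[2:] - c[:-2]) / (2 * dr * r[1:-1])
    # symmetric center (2-D polar): ∇²C|₀ = 4 (C₁ − C₀)/Δr²
    lap[0] = 4.0 * (c[1] - c[0]) / dr**2
    uptake = consumption * rho * c / (c + km) if km > 0 else consumption * rho * np.sign(c)
    c_new = c + dt * (diffusion * lap - uptake)
    c_new[-1] = 1.0  # fixed oxygenated boundary
    np.clip(c_new, 0.0, 1.0, out=c_new)
    return OxygenField(r_grid=r, concentration=c_new, time=oxy.time + dt)


def _radial_density(x: np.ndarray, y: np.ndarray, r_grid: np.ndarray, rho_ref: float,
                    cap: float = 0.3) -> np.ndarray:
    """Relative areal density of agents on the oxygen grid nodes, capped at
    ``cap`` × the core reference: cells sit in a crowded monolayer over most
    of the colony, so areal oxygen uptake saturates with coverage rather
    than growing linearly into the dense center."""
    dr = r_grid[1] - r_grid[0]
    r = np.hypot(x, y)
    edges = np.concatenate([[0.0], r_grid + dr / 2.0])
    counts, _ = np.histogram(r, bins=edges)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    rho = counts / areas
    if rho_ref > 0:
        rho = rho / rho_ref
    return np.minimum(rho, cap)


# ---------------------------------------------------------------------------
# Agent stepping
# ---------------------------------------------------------------------------

def _state_speeds(state: np.ndarray, params: ColonyParams, t: float) -> np.ndarray:
    speeds = np.zeros(len(state))
    speeds[state == STATE_ELONGATED] = params.base_speed
    speeds[state == STATE_CORONA] = params.corona_speed(t)
    return speeds


def _headings(
    x: np.ndarray, y: np.ndarray, state: np.ndarray, params: ColonyParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-agent heading angles; biased states draw von Mises noise around
    the outward radial direction."""
    outward = np.arctan2(y, x)
    theta = np.empty(len(x))
    for code, kappa in ((STATE_ELONGATED, params.intermediate_kappa),
                        (STATE_CORONA, params.ring_kappa)):
        m = state == code
        if not np.any(m):
            continue
        if kappa >= KAPPA_CAP:
            noise = np.zeros(int(m.sum()))  # concentration limit: exact mean direction
        elif kappa <= 0:
            noise = rng.uniform(-np.pi, np.pi, size=int(m.sum()))
        else:
            noise = rng.vonmises(0.0, kappa, size=int(m.sum()))
        theta[m] = outward[m] + noise
    theta[state == STATE_ROUNDED] = 0.0
    return theta


def step_agents(
    agents: pd.DataFrame,
    oxy: Optional[OxygenField],
    params: ColonyParams,
    dt: float,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Advance an agent table by one step of ``dt`` minutes.

    Rounded agents stay put; elongated agents random-walk at ``base_speed``;
    corona agents step at the corona state speed with von Mises headings
    about the outward radial direction.  Division (if ``division_rate`` > 0)
    duplicates agents in place with fresh ids.  Agents never violate the
    per-step displacement bound speed × dt.  Agents leaving the frame are
    kept (they are simply not rendered).

    This is the functional single-step surface; :func:`simulate` drives the
    same update in a loop with managed random streams.
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])
    t = float(agents["t_min"].iloc[0]) if len(agents) else 0.0
    x = agents["x_um"].to_numpy(dtype=float, copy=True)
    y = agents["y_um"].to_numpy(dtype=float, copy=True)
    state = agents["state"].to_numpy(dtype=np.int8, copy=True)
    ids = agents["id"].to_numpy(dtype=np.int64, copy=True)
    alive = agents["alive"].to_numpy(dtype=bool, copy=True)

    x, y = _move(x, y, state, params, t, dt, rng)
    x, y, state, ids, alive = _divide(x, y, state, ids, alive, params, dt, rng,
                                      next_id=int(ids.max()) + 1 if len(ids) else 0)
    return pd.DataFrame(
        {"id": ids, "t_min": t + dt, "x_um": x, "y_um": y, "state": state, "alive": alive}
    )


def _move(x, y, state, params, t, dt, rng):
    theta = _headings(x, y, state, params, rng)
    speeds = _state_speeds(state, params, t)
    return x + speeds * dt * np.cos(theta), y + speeds * dt * np.sin(theta)


def _divide(x, y, state, ids, alive, params, dt, rng, next_id):
    if params.division_rate <= 0:
        return x, y, state, ids, alive
    p = params.division_rate * dt / 60.0
    dividing = alive & (rng.uniform(size=len(x)) < p)
    k = int(dividing.sum())
    if k == 0:
        return x, y, state, ids, alive
    new_ids = np.arange(next_id, next_id + k, dtype=np.int64)
    x = np.concatenate([x, x[dividing]])
    y = np.concatenate([y, y[dividing]])
    state = np.concatenate([state, state[dividing]])
    ids = np.concatenate([ids, new_ids])
    alive = np.concatenate([alive, np.ones(k, dtype=bool)])
    return x, y, state, ids, alive


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_frame(
    agents: pd.DataFrame,
    params: ColonyParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one 8-bit bright-field-like frame from an agent table.

    Each in-view agent is a radially symmetric Gaussian intensity bump
    (σ = cell_render_radius / 2) of height ``render_amplitude`` on a flat
    background, with additive Gaussian noise of sd ``noise_sd``, clipped to
    [0, 255].  Agents whose bump would extend past the frame edge are
    treated as out of view and skipped.
    """
    size = params.image_size
    frame = np.full((size, size), params.render_background, dtype=np.float32)
    if len(agents):
        _add_bumps(
            frame,
            agents["x_um"].to_numpy(dtype=float),
            agents["y_um"].to_numpy(dtype=float),
            params,
        )
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng([params.seed, 2])
        frame += rng.standard_normal(frame.shape, dtype=np.float32) * np.float32(params.noise_sd)
    np.clip(frame, 0, 255, out=frame)
    return frame.astype(np.uint8)


def _add_bumps(frame: np.ndarray, x: np.ndarray, y: np.ndarray, params: ColonyParams) -> None:
    size = params.image_size
    ps = params.pixel_size
    half = params.half_width
    sigma_px = (params.cell_render_radius / 2.0) / ps
    h = max(1, int(np.ceil(1.6 * params.cell_render_radius / ps)))
    # fractional pixel coordinates (pixel centers at (j + 0.5)·ps − half)
    fx = (x + half) / ps - 0.5
    fy = (y + half) / ps - 0.5
    cx = np.rint(fx).astype(np.int64)
    cy = np.rint(fy).astype(np.int64)
    inview = (cx >= h) & (cx < size - h) & (cy >= h) & (cy < size - h)
    if not np.any(inview):
        return
    fx, fy, cx, cy = fx[inview], fy[inview], cx[inview], cy[inview]
    offs = np.arange(-h, h + 1)
    dx = cx[:, None] + offs[None, :] - fx[:, None]          # (N, k)
    dy = cy[:, None] + offs[None, :] - fy[:, None]
    gx = np.exp(-0.5 * (dx / sigma_px) ** 2)
    gy = np.exp(-0.5 * (dy / sigma_px) ** 2)
    patch = params.render_amplitude * gy[:, :, None] * gx[:, None, :]   # (N, k, k)
    rows = cy[:, None] + offs[None, :]
    cols = cx[:, None] + offs[None, :]
    flat_idx = (rows[:, :, None] * size + cols[:, None, :]).ravel()
    np.add.at(frame.reshape(-1), flat_idx, patch.astype(np.float32).ravel())


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Ground truth plus lazy rendering for one synthetic run.

    ``agents`` holds snapshots of every agent at every recorded frame time.
    Frames are rendered on demand (deterministically, from per-frame random
    streams) so long runs never hold a full image stack in memory unless
    :meth:`image_stack` is called.
    """

    params: ColonyParams
    agents: pd.DataFrame
    frame_times: np.ndarray
    ring_truth: pd.DataFrame          # columns: t_min, r_um (NaN = no ring)
    oxygen: Optional[List[OxygenField]] = None
    _by_frame: Optional[list] = field(default=None, repr=False)

    def _frames_index(self) -> list:
        if self._by_frame is None:
            order = {t: i for i, t in enumerate(self.frame_times)}
            groups = [None] * len(self.frame_times)
            for t, g in self.agents.groupby("t_min", sort=True):
                groups[order[float(t)]] = g
            self._by_frame = groups
        return self._by_frame

    def agents_at(self, i: int) -> pd.DataFrame:
        """Agent table snapshot at frame index ``i``."""
        return self._frames_index()[i]

    def render(self, i: int) -> np.ndarray:
        rng = np.random.default_rng([self.params.seed, 2, i])
        return render_frame(self.agents_at(i), self.params, rng=rng)

    def iter_frames(self) -> Iterator[np.ndarray]:
        for i in range(len(self.frame_times)):
            yield self.render(i)

    def image_stack(self) -> ImageStack:
        frames = np.stack([self.render(i) for i in range(len(self.frame_times))])
        return ImageStack(frames=frames, pixel_size=self.params.pixel_size,
                          frame_times=self.frame_times)

    def ring_radius_at(self, t: float) -> float:
        """Ground-truth ring radius at (or nearest to) time t, μm."""
        tt = self.ring_truth["t_min"].to_numpy()
        rr = self.ring_truth["r_um"].to_numpy()
        return float(rr[int(np.argmin(np.abs(tt - t)))])


def simulate(params: ColonyParams) -> SimulationResult:
    """Run a full synthetic colony experiment.

    Agents advance at ``step_dt``; snapshots are recorded at the requested
    frame times (linear interpolation inside a step, so motion is straight
    between successive agent updates — matching persistent cell motion on
    the sub-minute scale).  Returns ground truth trajectories, the ring
    trajectory (prescribed in kinematic mode, the corona-cohort mean radius
    in mechanistic mode), and the oxygen field series in mechanistic mode.
    """
    p = params
    duration = p.duration_min
    if p.mode == "kinematic" and duration < p.ring_formation_time:
        warnings.warn("duration is shorter than ring_formation_time; the ring never forms")
    frame_times = p.recording_times()
    frame_times = frame_times[frame_times <= duration + 1e-9]

    rng_init = np.random.default_rng([p.seed, 0])
    rng_step = np.random.default_rng([p.seed, 1])
    init = make_colony(p, rng=rng_init)
    x = init["x_um"].to_numpy(copy=True)
    y = init["y_um"].to_numpy(copy=True)
    state = init["state"].to_numpy(dtype=np.int8, copy=True)
    ids = init["id"].to_numpy(copy=True)
    alive = init["alive"].to_numpy(dtype=bool, copy=True)
    next_id = int(ids.max()) + 1 if len(ids) else 0

    # --- mechanistic set-up -------------------------------------------
    oxy = None
    oxy_series: Optional[List[OxygenField]] = None
    rho_ref = 1.0
    migratory = np.zeros(len(x), dtype=bool)  # permanent corona membership
    if p.mode == "mechanistic":
        r_max = p.drop_radius + 300.0
        n_nodes = int(np.ceil(r_max / p.oxygen_dr)) + 1
        r_grid = np.arange(n_nodes) * p.oxygen_dr
        oxy = OxygenField(r_grid=r_grid, concentration=np.ones(n_nodes), time=0.0)
        r0 = np.hypot(x, y)
        core = r0 < 0.25 * p.drop_radius if p.drop_radius > 0 else np.ones(len(x), bool)
        area = np.pi * (0.25 * p.drop_radius) ** 2 if p.drop_radius > 0 else 1.0
        rho_ref = max(core.sum() / area, 1e-12)
        oxy_series = []

    snapshots = []
    ring_r = np.full(len(frame_times), np.nan)
    fi = 0  # next frame index to record

    def record(idx, t_snap, xs, ys):
        snapshots.append(pd.DataFrame({
            "id": ids, "t_min": t_snap, "x_um": xs, "y_um": ys,
            "state": state.copy(), "alive": alive.copy(),
        }))
        if p.mode == "kinematic":
            ring_r[idx] = p.ring_radius(np.array([t_snap]))[0]
        elif p.mode == "mechanistic":
            m = state == STATE_CORONA
            ring_r[idx] = float(np.hypot(xs[m], ys[m]).mean()) if np.any(m) else np.nan
        if oxy_series is not None:
            oxy_series.append(OxygenField(oxy.r_grid, oxy.concentration.copy(), t_snap))

    if fi < len(frame_times) and abs(frame_times[fi]) < 1e-9:
        record(fi, 0.0, x.copy(), y.copy())
        fi += 1

    n_steps = int(np.ceil(duration / p.step_dt - 1e-9))
    corona_assigned = False
    dt_oxy = None
    if p.mode == "mechanistic":
        dt_oxy_max = max_stable_dt(p.oxygen_dr, p.oxygen_diffusion)
        n_sub = max(1, int(np.ceil(p.step_dt / dt_oxy_max)))
        dt_oxy = p.step_dt / n_sub

    for k in range(n_steps):
        t0 = k * p.step_dt
        t1 = min((k + 1) * p.step_dt, duration)
        dt = t1 - t0

        # --- state transitions at the start of the step ----------------
        if p.mode == "kinematic" and not corona_assigned and t0 + dt >= p.ring_formation_time - 1e-9:
            # conserved cohort: every non-rounded agent from just inside the
            # assembly radius outward — the corona is the colony's outermost
            # structure, nothing stays behind beyond it
            r = np.hypot(x, y)
            band = (r >= p.ring_start_radius - p.corona_band) & (state != STATE_ROUNDED)
            state[band] = STATE_CORONA
            corona_assigned = True
        elif p.mode == "mechanistic":
            rho = _radial_density(x, y, oxy.r_grid, rho_ref, p.oxygen_density_cap)
            n_sub = max(1, int(np.ceil(dt / max_stable_dt(p.oxygen_dr, p.oxygen_diffusion))))
            for _ in range(n_sub):
                oxy = step_oxygen(oxy, rho, dt / n_sub, p.oxygen_diffusion,
                                  p.oxygen_consumption, p.oxygen_km)
            r = np.hypot(x, y)
            c_local = oxy.at(r)
            grad = np.abs(oxy.gradient_at(r))
            # minimal aerotaxis trigger: critically hypoxic but not yet
            # rounded, and in the presence of an appreciable gradient
            trigger = ((c_local < p.c_crit) & (c_local >= p.c_round)
                       & (grad > p.grad_crit) & ~migratory)
            migratory |= trigger
            state[migratory] = STATE_CORONA
            rounded = (~migratory) & (c_local < p.c_round)
            state[rounded] = STATE_ROUNDED
            state[(~migratory) & (~rounded) & (state == STATE_ROUNDED)] = STATE_ELONGATED

        x_prev, y_prev = x, y
        x, y = _move(x, y, state, p, t0, dt, rng_step)

        # --- record frames that fall inside (t0, t1] -------------------
        while fi < len(frame_times) and frame_times[fi] <= t1 + 1e-9:
            tf = frame_times[fi]
            w = (tf - t0) / dt if dt > 0 else 1.0
            record(fi, float(tf), x_prev + w * (x - x_prev), y_prev + w * (y - y_prev))
            fi += 1

        # --- division at the end of the step ---------------------------
        if p.division_rate > 0:
            x, y, state, ids, alive = _divide(x, y, state, ids, alive, p, dt, rng_step, next_id)
            next_id = int(ids.max()) + 1
            if p.mode == "mechanistic" and len(migratory) != len(x):
                migratory = np.concatenate(
                    [migratory, np.zeros(len(x) - len(migratory), dtype=bool)])

    agents = pd.concat(snapshots, ignore_index=True) if snapshots else pd.DataFrame(columns=AGENT_COLUMNS)
    ring_truth = pd.DataFrame({"t_min": frame_times, "r_um": ring_r})
    return SimulationResult(params=p, agents=agents, frame_times=frame_times,
                            ring_truth=ring_truth, oxygen=oxy_series)


def states_to_names(codes) -> np.ndarray:
    """Map integer state codes to their names (for CSV export)."""
    arr = np.asarray(codes, dtype=int)
    out = np.empty(arr.shape, dtype=object)
    for code, name in STATE_NAMES.items():
        out[arr == code] = name
    return out
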