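"""Generative parameters for synthetic aerotaxis colonies.

A :class:`ColonyParams` fully specifies a synthetic experiment: colony
geometry, the motility regimes (rounded core / elongated intermediate zone /
outward-moving corona), either a prescribed ring trajectory (kinematic mode)
or an oxygen diffusion–consumption model (mechanistic mode), optional cell
division, and bright-field-like rendering.  Identical parameters (including
the seed) always produce bit-identical simulations.

Shipped presets are calibrated to the kinematics reported for confined
*Dictyostelium discoideum* colonies: the wild-type AX2 ring forms after
~60 min and propagates at 2.2 μm/min initially, slowing to 0.67 μm/min in
the 10–24 h regime; the catalase-null mutant responds faster (~28 min);
unconfined colonies spread at ~0.8 μm/min; spontaneous single-cell motility
is ~3.9 μm/min.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import i0e, i1e

__all__ = ["ColonyParams", "PRESETS", "get_preset", "mean_resultant", "KAPPA_CAP"]

#: von Mises concentrations above this are clamped (sampler stays finite).
KAPPA_CAP = 500.0

MODES = ("kinematic", "mechanistic", "unconfined", "uniform")
STATE_ROUNDED, STATE_ELONGATED, STATE_CORONA = 0, 1, 2
STATE_NAMES = {STATE_ROUNDED: "rounded", STATE_ELONGATED: "elongated", STATE_CORONA: "corona"}


def mean_resultant(kappa: float) -> float:
    """A(κ) = I₁(κ)/I₀(κ), the mean cosine of a von Mises(0, κ) heading.

    Uses exponentially scaled Bessel functions, stable for large κ.
    A(0) = 0 (uniform headings), A(κ) → 1 as κ → ∞.
    """
    if kappa <= 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


@dataclass
class ColonyParams:
    """Full generative parameter set for one synthetic colony run.

    Distances are μm, times minutes unless suffixed otherwise; rates noted
    per field.  ``duration_h`` is in hours to match the experimental
    convention of 24-h movies.
    """

    mode: str = "kinematic"
    n_cells: int = 4000
    drop_radius: float = 1200.0          # μm, radius of the seeded drop
    core_radius: float = 500.0           # μm, rounded (stationary) core
    ring_start_radius: float = 1050.0    # μm, where the corona assembles
    corona_band: float = 75.0            # μm, half-width of the recruited cohort
    ring_formation_time: float = 60.0    # min (kinematic mode)
    ring_speed_initial: float = 2.2      # μm/min
    ring_speed_late: float = 0.67        # μm/min
    speed_crossover_time: float = 600.0  # min
    base_speed: float = 3.9              # μm/min, random-motility speed
    ring_kappa: float = 0.4935           # von Mises κ of corona headings
    intermediate_kappa: float = 0.0      # κ of elongated-cell headings (0 = unbiased)
    division_rate: float = 0.0           # 1/h, in-place duplication
    duration_h: float = 24.0
    step_dt: float = 1.0                 # min, agent time step
    frame_interval: float = 1.0          # min, recording cadence
    frame_times: Optional[tuple] = None  # explicit recording times (min), overrides cadence
    pixel_size: float = 2.0              # μm/px
    image_size: int = 2048               # px (square frames)
    cell_render_radius: float = 5.0      # μm, Gaussian bump scale (σ = radius/2)
    render_amplitude: float = 120.0      # intensity of one cell at its center
    render_background: float = 8.0       # background intensity level
    noise_sd: float = 0.5                # additive Gaussian noise, 8-bit units
    seed: int = 0
    # --- mechanistic (oxygen) mode ---------------------------------------
    oxygen_diffusion: float = 800.0      # μm²/min, effective radial diffusivity
    oxygen_consumption: float = 0.20     # 1/min at unit relative density
    oxygen_km: float = 0.05              # Michaelis constant, fraction of air sat.
    oxygen_dr: float = 15.0              # μm, radial grid spacing
    oxygen_density_cap: float = 0.15     # areal uptake saturates with coverage
    c_round: float = 0.02                # below this cells round up
    c_crit: float = 0.10                 # below this (with a gradient) cells migrate
    grad_crit: float = 1e-3              # 1/μm, minimum |dC/dr| to trigger migration

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.drop_radius < 0:
            raise ValueError("drop_radius must be >= 0")
        if self.mode != "uniform" and self.drop_radius == 0 and self.n_cells > 0:
            pass  # degenerate disc is allowed: all agents at the center
        for name in (
            "core_radius", "ring_start_radius", "corona_band",
            "ring_formation_time", "ring_speed_initial", "ring_speed_late",
            "speed_crossover_time", "base_speed", "division_rate",
            "duration_h", "cell_render_radius", "noise_sd",
            "oxygen_diffusion", "oxygen_consumption", "oxygen_km",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ring_start_radius > self.drop_radius and self.mode in ("kinematic", "mechanistic"):
            raise ValueError("ring_start_radius must not exceed drop_radius")
        if self.step_dt <= 0 or self.frame_interval <= 0:
            raise ValueError("step_dt and frame_interval must be positive")
        if self.pixel_size <= 0 or self.image_size <= 0:
            raise ValueError("pixel_size and image_size must be positive")
        self.ring_kappa = min(float(self.ring_kappa), KAPPA_CAP)
        self.intermediate_kappa = min(float(self.intermediate_kappa), KAPPA_CAP)
        if self.ring_kappa < 0 or self.intermediate_kappa < 0:
            raise ValueError("von Mises concentrations must be >= 0")

    # ------------------------------------------------------------------
    @property
    def duration_min(self) -> float:
        return self.duration_h * 60.0

    @property
    def half_width(self) -> float:
        """Half the physical field of view, μm."""
        return self.image_size * self.pixel_size / 2.0

    def recording_times(self) -> np.ndarray:
        """Frame times in minutes, strictly increasing, starting at 0."""
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
                raise ValueError("frame_times must be strictly increasing")
            return t
        n = int(math.floor(self.duration_min / self.frame_interval + 1e-9)) + 1
        return np.arange(n) * self.frame_interval

    def ring_radius(self, t) -> np.ndarray:
        """Prescribed ring radius R(t), μm (kinematic mode ground truth).

        Piecewise linear and continuous: R = ring_start_radius until the
        formation time, then advances at ring_speed_initial up to the
        crossover time and at ring_speed_late afterwards.  NaN before
        formation (no ring yet) and in modes without a prescribed ring.
        """
        t = np.asarray(t, dtype=float)
        if self.mode in ("unconfined", "uniform"):
            return np.full(t.shape, np.nan)
        t0, tc = self.ring_formation_time, self.speed_crossover_time
        r = np.full(t.shape, np.nan)
        formed = t >= t0
        early = formed & (t <= tc)
        late = t > tc
        r[early] = self.ring_start_radius + self.ring_speed_initial * (t[early] - t0)
        r[late] = (self.ring_start_radius
                   + self.ring_speed_initial * (max(tc - t0, 0.0))
                   + self.ring_speed_late * (t[late] - tc))
        return r

    def ring_speed(self, t: float) -> float:
        """dR/dt of the prescribed ring at time t (0 before formation)."""
        if self.mode in ("unconfined", "uniform") or t < self.ring_formation_time:
            return 0.0
        return self.ring_speed_initial if t <= self.speed_crossover_time else self.ring_speed_late

    def corona_speed(self, t: float) -> float:
        """State speed of corona agents so that the cohort mean radius
        advances at the prescribed ring speed: s = v_ring / A(ring_kappa)."""
        a = mean_resultant(self.ring_kappa)
        v = self.ring_speed(t) if self.mode == "kinematic" else self.ring_speed_initial
        if a <= 0:
            return v  # κ=0: pure diffusion, no drift is achievable; fall back
        return v / a

    # ------------------------------------------------------------------
    def replace(self, **overrides) -> "ColonyParams":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["frame_times"] is not None:
            d["frame_times"] = list(d["frame_times"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ColonyParams":
        d = dict(d)
        if d.get("frame_times") is not None:
            d["frame_times"] = tuple(d["frame_times"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Presets.  Speeds/times are the printed reference kinematics; geometry is a
# desk-scale colony (drop radius 1.2 mm instead of the experimental ~2.8 mm).
# ---------------------------------------------------------------------------

PRESETS: dict = {
    # Wild-type confined colony: ring forms at 60 min, 2.2 μm/min initial,
    # 0.67 μm/min after the 10-h crossover.  pixel_size 3.5 so the 2048-px
    # frame (half-width 3584 μm) holds the ring and its spread out to 24 h
    # (peak ~2850 μm).  The corona assembles from the outermost part of the
    # colony (everything beyond ring_start − corona_band).
    "AX2-confined": dict(
        mode="kinematic",
        n_cells=5000,
        corona_band=75.0,
        pixel_size=3.5,
        ring_formation_time=60.0,
        ring_speed_initial=2.2,
        ring_speed_late=0.67,
        speed_crossover_time=600.0,
        duration_h=24.0,
    ),
    # Catalase-null mutant: hypoxia response roughly twice as fast
    # (formation ~28 min), moderately higher initial speed.
    "catA-confined": dict(
        mode="kinematic",
        n_cells=5000,
        corona_band=75.0,
        pixel_size=3.5,
        ring_formation_time=28.0,
        ring_speed_initial=2.5,
        ring_speed_late=0.67,
        speed_crossover_time=600.0,
        duration_h=24.0,
        # mechanistic overrides: catalase loss → H2O2 accumulation → faster
        # consumption-driven response at a milder hypoxia threshold
        oxygen_consumption=0.36,
        c_crit=0.20,
    ),
    # Unconfined control: no ring.  A weak outward heading bias
    # (A(0.125) ≈ 0.062; the sliding-window *maximum* statistic has an
    # extreme-value upward bias of ~+0.02, so the measured ceiling lands at
    # the reference 0.08) plus division (doubling ~8 h) drive an emergent
    # border expansion inside the 0.8 ± 0.3 μm/min reference band.
    "NC-spreading": dict(
        mode="unconfined",
        n_cells=5000,
        drop_radius=2000.0,
        core_radius=0.0,
        pixel_size=3.0,
        image_size=1536,
        intermediate_kappa=0.125,
        division_rate=math.log(2) / 8.0,  # 1/h
        duration_h=5.0,
    ),
    # Sparse uniformly scattered cells for the spontaneous-motility assay.
    "uniform-motility": dict(
        mode="uniform",
        n_cells=350,
        base_speed=3.9,
        pixel_size=2.0,
        image_size=1024,
        duration_h=0.5,
        frame_interval=1.0 / 3.0,
    ),
}


def get_preset(name: str, **overrides) -> ColonyParams:
    """Instantiate a shipped preset, optionally overriding fields."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ColonyParams(**kwargs)
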