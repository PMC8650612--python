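# Methods

`coronakit` quantifies the collective escape of a confined cell colony from
self-generated hypoxia: a dense ring of cells (the *corona*) detaches from
the colony and propagates outward along the oxygen gradient.  The package
couples a measurement pipeline (images → densities → ring kinetics →
single-cell statistics) to a synthetic colony generator with exact ground
truth, so every estimator is validated by parameter recovery.  This note
records the models, the defaults and why they are what they are, and what
the synthetic validation does and does not demonstrate.

## 1. The synthetic colony

### Geometry and placement

A colony is a disc of `n_cells` agents (default 5,000 at desk scale,
standing in for the ~50,000-cell experimental drop).  Radial positions
follow a half-Gaussian (sd = 0.6 × `drop_radius`) truncated at the drop
radius, with uniform angles; the expected areal density therefore decreases
monotonically from the center, as observed at seeding.  The default drop
radius is 1.2 mm (the experimental drop is ~2.8 mm; everything scales
accordingly).  Confined presets render at 3.5 μm/px on 2048² frames so the
field of view (±3,584 μm) holds the ring and its diffusive spread through
24 h.

### Motility states

Agents carry one of three states:

* **rounded** — severely hypoxic cells; zero displacement.
* **elongated** — random motility at `base_speed` (3.9 μm/min, the
  spontaneous speed of growing cells).  Headings are drawn per step from a
  von Mises distribution centered on the outward radial direction with
  concentration `intermediate_kappa`; the default κ = 0 is the uniform
  circle, i.e. an unbiased random walk.
* **corona** — directed migration: von Mises headings about outward with
  κ = `ring_kappa`, at the corona state speed.

For a von Mises heading with concentration κ, the mean cosine relative to
outward is A(κ) = I₁(κ)/I₀(κ).  Two consequences drive the calibration:

* the mean radial drift of a corona cell is `speed × A(κ)`, so the state
  speed is set to `v_ring / A(ring_kappa)` and the cohort's mean radius
  tracks the prescribed ring trajectory exactly in expectation;
* the per-step directionality ratio v_r/|v| has mean A(κ), so
  `ring_kappa = 0.4935` (A = 0.24) reproduces the reference corona
  directionality, and the unconfined preset's `intermediate_kappa = 0.125`
  (A ≈ 0.062) reproduces the reference unconfined ceiling of 0.08 once the
  extreme-value bias of the max-over-radius statistic (≈ +0.02 at these
  sample sizes) is accounted for.  The reference value is itself a maximum
  over a sliding-window profile and carries the same bias, which is why
  the underlying bias is set below the printed number.

At the κ cap (500) the sampler degenerates to the exact mean direction, so
"κ → ∞" behaves as the concentration limit rather than sampling noise.

Agents step every `step_dt` (1 min) and move in a straight line within a
step; recorded frames between steps interpolate linearly.  Cell motion is
therefore persistent on the sub-minute scale, matching the premise of
per-minute velocimetry.  Division, when enabled, duplicates an agent in
place with a fresh id at rate `division_rate` (the unconfined preset uses
ln 2 / 8 h, a typical axenic doubling time).

### Kinematic mode (estimator recovery)

The ring trajectory is prescribed and piecewise linear: R(t) =
`ring_start_radius` until `ring_formation_time`, then advancing at
`ring_speed_initial` until `speed_crossover_time` and `ring_speed_late`
afterwards.  At formation, every non-rounded agent beyond
`ring_start_radius − corona_band` (75 μm) switches permanently to the
corona state: a conserved cohort, matching the observation that the ring
neither recruits nor sheds cells in the late regime, and one that includes
the colony's outermost cells — the corona is the outermost structure of
the colony, so no stationary shell is left beyond it (a residual outer
shell would bias the detected peak for the first hours after formation).
`ring_start_radius` defaults to 1,050 μm, near the colony edge: starting
the ring where the colony background is thin minimizes the bias that a
sloping background exerts on the detected peak position.

### Mechanistic mode (emergent ring)

A radial oxygen field C(r, t) (fraction of air saturation) obeys

    ∂C/∂t = D (C'' + C'/r) − k ρ(r) · C/(C + K_m)

solved by explicit finite differences (Δr = 15 μm, sub-stepped to the
stability bound dt ≤ Δr²/4D) with a symmetric node at r = 0 and the outer
boundary pinned at 1.0.  ρ(r) is the relative areal cell density, capped
at `oxygen_density_cap` = 0.15 of the central reference: cells sit in a
crowded monolayer over most of the colony, so areal uptake saturates with
coverage instead of growing into the dense center.  The cap is what lets
hypoxia extend toward the colony periphery rather than collapsing into a
narrow central pit.

State rules per step: cells with C < `c_round` (0.02) round up; cells with
`c_round` ≤ C < `c_crit` in the presence of a gradient (|dC/dr| >
`grad_crit` = 10⁻³ μm⁻¹) switch permanently to the corona state.  The ring
and its formation time are then emergent.  The shipped presets are
calibrated so the *detected* formation time reproduces the reference
kinetics: wild type D = 800 μm²/min, k = 0.20 min⁻¹, `c_crit` = 0.10
(T* ≈ 60 min); the catalase-null preset uses k = 0.36 and `c_crit` = 0.20
— intracellular peroxide accumulation makes the mutant respond faster and
at milder hypoxia — giving T* ≈ 28 min.  All other constants were fixed
before calibration; the consumption rate (and, for the mutant, the
response threshold) are the calibration knobs.

A note on an intuitive invariant: with a fixed oxygenated boundary and
consumption-only kinetics, min_r C(r) is non-increasing — but only while
the density field is stationary.  Once the corona departs, consumption
falls where cells vacated and the minimum can recover; the property is
asserted for frozen density only.

### Rendering

Each in-view agent is a Gaussian intensity bump (σ = `cell_render_radius`/2
= 2.5 μm, amplitude 120) on a flat background of 8, plus Gaussian noise
(sd 0.5), clipped to 8 bits.  These are clean-microscopy settings: the
binarization offset (2 intensity units, 4 standard deviations of noise)
then keeps the false-foreground rate negligible, which matters because the
late-time ring is only ~1–2 density-percent above an empty background.

## 2. The measurement pipeline

**Binarization.**  A pixel is foreground iff it exceeds the local
block-mean (51 px, arithmetic mean) by strictly more than the offset.  A
constant image yields an all-background mask.  Polarity is configurable
for dark-cell imagery.

**Profiles.**  The colony center is the foreground centroid of the first
frame, reused for all later frames so radii remain comparable.  Radial
profiles are per-annulus brightness fractions × 100 with half-open 30-μm
bins; annuli clipped by the frame use the in-frame pixel count as
denominator, so edge annuli are area-corrected rather than biased low.

**Ring detection.**  Profiles are smoothed with a 5-bin moving average
(the smoothing breadth is a free analysis choice; wider smoothing keeps
the detected maximum of an asymmetric, relaxing ring profile close to its
centroid);
the ring is the outermost local maximum beyond `peripheral_fraction` (0.5)
of the colony radius (the outermost radius at ≥ 2% of the profile maximum,
measured at t = 0) whose prominence exceeds the noise floor.  The floor is
the larger of twice the bin-to-bin difference sd in the outermost (empty)
annuli and an absolute 0.5 density-percent: a colony of finitely many
cells carries Poisson texture in its interior annuli that the empty-edge
estimate cannot see, and texture bumps reach a few tenths of a percent.
The peak radius is refined to sub-bin precision by parabolic interpolation
through the peak bin and its neighbors.

**Formation time.**  T* is the first time the ring is detected in
`persistence` = 3 consecutive frames, measured from confinement start; the
latency bound (persistence × frame interval) is reported with it.  In a
small synthetic colony the ring additionally needs to separate from the
colony texture before it can register, bounded by
(drop_radius − ring_start + one bin)/v_i.

**Speeds.**  v_i is the mean per-interval peak velocity within
[T*, T* + 140 min] (for uniform sampling this equals ΔR over the realized
span).  Two conventions exist for this window — the first two hours after
formation, or the first 140 min — and the package defaults to 140 min with
the window exposed as a flag.  v_f is the ordinary least-squares slope of
R(t) on 10–24 h, unweighted.  Both are exact on noiseless piecewise-linear
traces.

**Ring geometry.**  The ring extent at each time is the contiguous radial
interval around the peak with density above a floor (default: the baseline
flanking the ring plus half the peak height above it; an absolute floor
can be supplied).  Width and mean ring density are resampled to a 6-min
cadence and binned five measurements per reported point (mean ± sd).  The
area-conservation model for a constant-density conserved ring predicts
L(t) = L₀R₀/R(t); the product R·L is conserved to 10⁻⁹ relative tolerance.

**Unconfined expansion.**  The border at threshold *th* is the outermost
radius with density ≥ *th* (sub-bin interpolated); per-minute border
velocities over the first 5 h are averaged per threshold and then across
the sweep — nine thresholds, 10–50% of the t = 0 central density in 5%
steps.  For a rigidly translating profile the estimate is
threshold-independent.  At desk scale the expansion is emergent from the
weak outward bias plus division; the division contribution scales with
colony size, so the recovered v_NC sits in the lower half of the 0.8 ± 0.3
μm/min reference band.

**Duplication.**  Cell counts in a fixed circular sector: by symmetry
there is no net flux through a sector, so the ratio N(t)/N(t_ref)
(reference 10 h) isolates division.  A well-mixed sector tracks
exp(g·(t − t_ref)).

**Tracking.**  Spot detection is band-pass (difference of Gaussians at the
10-μm feature scale) followed by local maxima at least one radius apart,
intensity-weighted centroid refinement, and an integrated-mass cut (for
rendered frames, a quarter of one cell's integrated intensity).  Linking
is greedy nearest-neighbor: candidate pairs within max_speed × Δt
(10 μm/min) accepted in global distance order, no gap closing.  The
protocol is 30 min at 3 frames/min starting mid-run (270 min).

**Velocimetry.**  Speeds are measured over *disjoint* 1-min periods
aligned to a common grid; the in-between frames serve linking only.  This
matters: sliding 1-min windows at 3 frames/min straddle two independent
motion segments two-thirds of the time and understate the speed of
minute-persistent cells by ~20%.  v_r projects the step on the outward
unit vector at the interval start; |v_r| ≤ |v| identically.  The
directionality ratio v_r/|v| is excluded when |v| < 0.5 μm/min — the
direction of a near-zero step is noise; set the floor to 0 to keep such
samples.  Sliding-window profiles use a 150-μm window stepped by 25 μm;
windows with fewer than 300 samples are undefined.  The 300-sample floor
(not 20) is deliberate: a mean of 20 signed cosines has an sd of ≈ 0.16,
which would let pure noise dominate a max-over-radius statistic whose
interesting values are 0.08 vs 0.24.

**Circular statistics.**  Step headings are measured relative to the
outward radial direction (μ = 0 means outward).  The von Mises fit uses
μ̂ = circular mean and κ̂ solving A(κ̂) = R̄ (free μ), or A(κ̂) = mean
cos(θ − μ) with κ̂ = 0 at non-positive values (fixed μ); the solver is
bracketed bisection to 10⁻⁸ with κ capped at 500.  A fixed-μ fit depends
on the data only through the mean cosine, so the ratio samples suffice.

## 3. Problem sizes and schedules

Desk-scale study conditions: ≤ 5,000 agents, ≤ 2048² px, 24 h of 1-min
steps.  The 24-h confined runs record one frame per minute through the
first 4 h (formation and the initial-speed window) and one per 8 min
afterwards — the late-phase OLS slope gains nothing from minute sampling.
Mechanistic formation-time runs cover the first 2.5 h (wild type) or 1.5 h
(catalase-null) since only the onset matters.  Recovery experiments
average 5 seeds (confined kinematics) or 2–3 seeds (others).

## 4. What the synthetic validation shows — and what it does not

Passing recovery tests demonstrate that the pipeline measures what it
claims on data whose ground truth is known: unbiased speed and formation
estimates at realistic density, noise and sampling, correct circular
statistics, and detection/linking that tolerate the rendered image model.
They do not validate the image model itself against real bright-field
movies: rendered cells are isotropic Gaussian bumps (no shape change
between rounded and elongated states, no optical artifacts, no
illumination drift), noise is white and Gaussian, the colony is perfectly
circular, and corona membership is binary and permanent.  The mechanistic
oxygen model is a minimal one-dimensional caricature chosen for its
qualitative structure (critical hypoxia plus gradient), with thresholds
that are free parameters, not measurements.

## 5. Known limitations

* No cell–cell mechanics: agents overlap freely; density saturation is
  emulated only in rendering (overlap) and oxygen uptake (cap).
* The kinematic corona cohort spreads diffusively (radial sd ≈ 160 μm by
  24 h), so the late-time ring is broader and fainter than a real corona;
  detection thresholds were chosen with this in mind.
* Lineage is not tracked through division, and linking has no gap closing;
  a missed detection terminates a track.
* The unconfined expansion velocity depends on colony scale through the
  division term; desk-scale values sit low in the reference band.
* Oxygen dynamics are radial (1-D): azimuthal heterogeneity, stream
  formation and aggregate fragmentation are out of scope.
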