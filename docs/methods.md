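# Methods

This note documents the model implemented by `glancecf`, its default
parametrization, the numerical choices, how the synthetic experiments
are generated, and the limitations of what we compute.  All numbers
quoted here are produced by this package's own code (test suite and
`scripts/acceptance.py`); no empirical claims about human data are made.

## 1. Model

### 1.1 State and percepts

The world state relevant to the driver is `x = (v, d, r)`: own speed
(m/s), bumper-to-bumper gap (m) and relative speed `r = vL − v` (m/s,
positive when the gap opens).  The driver receives, every `Δt = 0.1 s`:

- **Optic flow** `F = log(max(v, v_floor))`, `v_floor = 0.1 m/s`.
- **Angular width** of the lead car,
  `φ = 2·atan(u / (2(d + d₀)))` in degrees, with car width
  `u = 1.9 m` and eye-to-front-bumper distance `d₀ = 1.5 m`.
- **Angular expansion** (looming), the time derivative of `φ` along
  `d(t) = d + r t`:
  `v_φ = −4 u r / (4(d + d₀)² + u²)` (converted to deg/s).

Each percept channel carries additive Gaussian noise that is constant in
*percept* space (`σ_F = 0.3` log units, `σ_φ = 0.3°`,
`σ_vφ = 0.3°/s`).  Because the transforms are compressive, the implied
noise in metric units grows with the magnitude of the state — inverting
a noisy log-speed or angular-width sample yields errors that grow with
speed and (superlinearly) with distance; this Weber–Fechner-like
behaviour is asserted by tests.  While the view is occluded only `F` is
received.

### 1.2 Belief: bootstrap particle filter

The belief over `x` is carried by `N = 512` particles.

**Prediction.** Own speed propagates with an efference copy of the
previous acceleration command `a_prev`:
`â ~ N(a_prev, (λ_a·a_prev)²)` with `λ_a = 0.1`.  The unobservable
leader acceleration is modelled as `âL ~ N(0, σ_aL²)` with
`σ_aL = 4 m/s²`.  The gap advances by the particle's pre-update
relative speed, `d ← d + r·Δt`.  Predicted own and leader speeds are
clamped at zero (see section 4, deviations).

**Update.** Particle log-weights accumulate the Gaussian percept
log-likelihood in percept space; occluded steps use the flow term only.
Weights are normalized in log space with max-subtraction.  A particle
with `v < 0` or `d + d₀ ≤ 0` gets zero likelihood; if every particle
does, the trial aborts with a degenerate-posterior error.

**Resampling.** Systematic resampling runs every step: one uniform
offset, a comb of `N` equally spaced pointers over the cumulative
weights.  Offspring counts are exactly `⌊N·wᵢ⌋` or `⌈N·wᵢ⌉`
(acceptance criterion), which minimizes resampling variance among
single-offset schemes.

### 1.3 Control: IDM over the belief

Each particle is mapped through the Intelligent Driver Model:

```
a = a_max · [ 1 − (v / v_max)^δ − (s*(v, Δv) / d)² ]
s*(v, Δv) = s0 + max(0, s1·sqrt(v / v_max) + v·T + v·Δv / (2·sqrt(a_max·b_max)))
```

with `Δv = −r`.  Defaults: `v_max = 80 km/h`, `δ = 4`, `s0 = 2 m`,
`s1 = 0`, `b_max = a_max / 0.6`.  Particles whose believed gap is
non-positive contribute `−b_max` (they are transient and killed by the
likelihood).  The weighted mean `ā` of the per-particle accelerations is
actuated exactly (no motor noise); the weighted standard deviation
`σ_â` is the driver's **action uncertainty**.

### 1.4 Attention: uncertainty-triggered glances

The forward view is occluded by default.  When occluded and
`σ_â > σ_â*` (per-driver threshold, default `1 m/s²`), the driver
requests a glance: the view opens for `t_G = 0.3 s` and then re-occludes
automatically; a glance cannot re-trigger mid-glance.  On the 0.1 s grid
a glance is `n_G = 3` steps: the recorded occlusion flag is 0 on the
lift step and the two following steps, and leader percepts (width,
looming) are received on the two steps strictly after the lift — the
lift step itself is still sampled blind, modelling that the decision is
made before the view opens.

### 1.5 Environment and trial protocols

The lead car follows a piecewise speed protocol: targets drawn from
{20, 40, 60} km/h, switch intervals uniform on [20, 30] s, ramps of
±2 m/s² that snap to the target without overshoot.  Two protocols:
`real_car` (independent target draws, fixed 300 s duration) and `vr`
(nine segments, each target exactly three times in random order,
≈ 190–270 s).  Kinematics are forward-Euler at `Δt = 0.1 s` with speeds
clamped at zero; the gap integrates the pre-step relative speed.  A
trial ends at the protocol end or when `d ≤ 0` (collision).  The
follower starts at the first target speed with a 30 m gap and `r = 0`.

The belief is initialized with the true own speed, gap uniform on
[5, 200] m, and relative speed from a uniform leader-speed reading (see
section 4).

### 1.6 Calibration

Three parameters are driver-specific: `T`, `a_max`, `σ_â*`.  They are
estimated by simulation: a virtual dataset of trials with parameters
drawn uniformly from `T ∈ [0.1, 15] s`, `a_max ∈ [0.1, 8] m/s²`,
`σ_â* ∈ [0.1, 8] m/s²`, each trial summarized by median time headway,
median occlusion duration and the 99th percentile of signed actuated
acceleration.  A subject is summarized the same way (median of their
per-trial features), features are z-scored by the dataset statistics,
and the estimate is the mean parameter vector of the `k = 5` nearest
virtual trials.  Crashed virtual trials are kept and flagged; features
are computed over the steps before the crash.  Trials with fewer than
two glances have their occlusion feature censored at the trial duration.

### 1.7 Behavioural statistics

- Occlusion durations: differences between successive lift times minus
  `t_G`, floored at zero.
- Headway–occlusion pairing: the time headway `d/v` sampled at each
  glance step, paired with the duration of the occlusion that follows;
  near-standstill steps (`v < 0.1 m/s`) are excluded.
- Per-trial robust detrending: Theil–Sen slope with median intercept on
  both margins, removing slow drifts before correlating.
- Within-subject effect: Spearman rank correlation of the pooled
  detrended pairs across a subject's trials.
- Across subjects: exact two-sided sign test (doubled smaller binomial
  tail, capped at 1).
- Crash rates: Monte-Carlo fraction with exact Clopper–Pearson 95%
  intervals.

## 2. Numerical choices

- **Two engines, one stream.** The trial loop exists twice: a reference
  loop composed from the public per-operation functions, and a
  numba-compiled kernel used by default (`engine="fast"`, ≈ 80 ms per
  trial at 512 particles, making 5 000-trial virtual datasets affordable
  on one CPU).  Both consume the same seeded generator in the same
  per-step draw order (own-acceleration noise block, leader-noise block,
  three percept scalars, resampling offset), and a test asserts
  trajectory agreement to ≤ 1e−9 with identical glance sequences.
- **Log-space weights** with max-subtraction; constant likelihood terms
  cancel in the normalization and are omitted in the kernel.
- **Reproducibility.** Every run is a pure function of its arguments
  and one integer seed; sub-seeds are drawn below 2³¹.  Fixture
  generation is byte-identical per seed.
- **Filter validation oracle.** For the special case `a_prev = 0` (own
  speed known), the exact posterior lives on the `(d, r)` plane and is
  computed on a dense grid (shear of the gap axis + Gaussian convolution
  of the relative-speed axis for prediction; pointwise likelihood
  multiplication for the update) with transforms and densities coded
  independently of the filter (scipy).  Grid convergence was verified by
  halving the cell size.  The acceptance test requires particle-filter
  posterior means (N = 10⁵) within 3 Monte-Carlo standard errors of the
  grid oracle.

## 3. Generator realism for the synthetic experiments

The acceptance experiments simulate synthetic subjects rather than
replaying recordings, so the subject populations are package choices:

- *Parameter recovery* uses 20 subjects from the central half of the
  calibration prior box (avoiding edge bias of the k-NN mean at the
  prior boundary), two trials each, against a 5 000-trial virtual
  dataset — a scaled-down version of the full procedure.
- *Emergent correlation* uses 20 subjects from a realistic driver range
  (`T ∈ [1, 4] s`, `a_max ∈ [1, 3] m/s²`, `σ_â* ∈ [0.5, 3] m/s²`),
  three trials each.  With seed 2024 this yields 20/20 subjects with a
  positive detrended correlation, median ρ = 0.63.
- *Monotone trends* hold two of the three parameters fixed at mid-range
  values and vary the third over a coarse grid, with 10 trials per grid
  point and medians of per-trial medians as the summary.

## 4. Deviations and design decisions

These are the package's own choices where a literal reading of the
model description produced degenerate behaviour; they are the defaults
and can be switched off.

- **Relative-speed prior reads leader speed.** Initializing the belief
  with `r ~ U(20, 60) km/h` literally makes every particle believe the
  leader is *receding* at 20–60 km/h regardless of own speed; the driver
  then accelerates confidently, never glances, and crashes in ~40% of
  trials.  The default (`leader_speed_prior=True`) interprets the range
  as a leader-speed reading, `r = vL − v0` with `vL ~ U(20, 60) km/h`,
  which yields crash fractions of order 1% for mid-range drivers.  The
  literal prior remains available via `init_belief`/`SimulationConfig`.
- **Predicted speeds clamped at zero.** Without the clamp, a particle
  whose predicted own speed goes negative receives zero likelihood.
  Under extreme-but-in-prior calibration draws (e.g. `T ≈ 15 s`
  commanding hard braking near standstill) *all* particles can cross
  zero in one step, aborting the trial inside the calibration priors'
  own support.  The world model does not allow reversing, so the
  prediction clamps own and leader speed at zero, mirroring the
  environment.
- **Glance window bookkeeping** is integer-step (`n_G = round(t_G/Δt)`),
  so windows are exactly 3 steps and the acceptance check is exact.
- **Detrending method.** "Robust linear trend" is implemented as
  Theil–Sen; it is a single swappable function.
- **Headway at the glance step** (not averaged over the occlusion) is
  paired with the following occlusion duration.

## 5. Limitations

- All validation is against the model's own mechanics and synthetic
  data; no human dataset ships with the package, and nothing here
  asserts agreement with human recordings.
- The environment is a single-lane, straight-road world with exact
  actuation and forward-Euler kinematics at 0.1 s; there is no motor
  noise, no reaction-time lag beyond the filter dynamics, and no lateral
  control.
- Percept noise magnitudes are fixed constants; the model does not adapt
  them with context (luminance, eccentricity, workload).
- The k-NN calibration inherits the usual bias of nearest-neighbour
  averaging near prior boundaries; recovery numbers are quoted for the
  central half of the prior box.
- `a_max` is only weakly identified by the three features when glances
  are rare; the acceptance criterion targets the headway parameter.
- The grid oracle covers the `a_prev = 0` slice only; full
  three-dimensional posteriors are validated indirectly (moments,
  degeneracy handling, resampling exactness).
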