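# Methods

## The extended Hill module

The package is built around a single phenomenological primitive. An
ultrasensitive response is the Hill function

    Out = In^n / (K^n + In^n),

with threshold `K` (nM) and exponent `n` (default 15, the steepness regime
of the mitotic switches measured in frog egg extracts). Bending this into an
S-shaped (bistable) response is done by making the threshold depend on the
output through a scaling function ξ:

    Out = In^n / ((ξ(Out)·K)^n + In^n).

This relation is multivalued, so it is only ever used as the steady state of
a relaxation ODE, `ε dOut/dt = Hill(In; ξ(Out)K, n) − Out`, with relaxation
time `ε`. The default ξ is the cubic

    ξ(y) = 1 + α·y(y−1)(y−r),

which is exactly 1 at y = 0, r and 1. `α ≥ 0` (dimensionless) controls the
width of the bistable region — α = 0 recovers the plain Hill response — and
`r ∈ (0,1)` (default 0.5) its asymmetry. Quadratic, linear, piecewise-linear
and tabulated ξ kinds are also provided; the piecewise kind
(`x_max < x_min`, levels `ξ_max ≥ 1 ≥ ξ_min`) is what gets fitted to
tabulated response curves.

All curve geometry is computed on the *inverted* response
`In(y) = ξ(y)·K·(y/(1−y))^{1/n}`, which is single-valued. Folds are the
roots of `dIn/dy` on (0,1), bracketed on a 10⁴-point uniform grid and
refined by Brent's method to 1e−12; the S-region width is the input-axis
distance between the two folds (zero when fewer than two folds with
positive input exist; more than two folds is reported and flagged rather
than truncated).

**Positivity.** The ScalingFunction constructor rejects parameter
combinations for which ξ ≤ 0 anywhere on [0,1] (the threshold must remain
positive for the analysis operations). The one deliberate exception is the
CycB→Cdk1 switch, whose ξ argument is the activity *ratio* [Cdk1]/[CycB]:
checkpoint and circadian perturbations legitimately push its bend far beyond
the whole-interval bound (e.g. α_cdk = 30 during G2 damage), and only the
lower branch — where the shifted activation fold lives — is visited while
the perturbation is active. Scheduled or forced α values are therefore
validated on [0, 0.5] only (`modelzoo.validate_alpha_lower`).

## Model systems

Concentrations are nM, time is minutes, starred variables are activity
fractions in [0,1]. All initial conditions default to the all-low state
(everything 0), mirroring a fully reset cycle.

* **Embryonic two-variable oscillator** ([Cdk1], [APC]\*): constant cyclin
  synthesis `b_syn`, APC/C-dependent degradation `b_deg·[Cdk1]·[APC]*`, and
  the APC/C switch relaxation. Non-dimensionalization (concentration by
  `K_cdk,apc`, time by `1/b_deg`) leaves the relative synthesis
  `c = b_syn/(K_cdk,apc·b_deg)`, `ε* = ε·b_deg` and `τ* = b_deg·τ`.
  Standard values: `ε* = 0.01`, `n = 15`, `b_deg = 0.1/min`,
  `K_cdk,apc = 20 nM`.
* **Delayed variant**: the APC/C equation reads the lagged [Cdk1](t−τ).
  τ is constant (τ₁ = τ₂) or blends an activation delay τ₁ and an
  inactivation delay τ₂ through a Hill switch on the *current* [APC]\*
  (exponent p, default 5): τ([APC]\*) = τ₁ + (τ₂−τ₁)·Hill([APC]\*; 0.5, p).
* **Three-variable embryonic oscillator** adds the CycB→Cdk1 switch: its
  Hill term is multiplied by [CycB] (so [Cdk1] is an absolute concentration
  that keeps rising with [CycB] rather than saturating at 1) and ξ is
  evaluated at [Cdk1]/[CycB], guarded as [Cdk1]/max([CycB], 1e−12 nM).
  `K_cyc,cdk = 40 nM`.
* **Interlinked five-variable somatic model** ([CycD], [E2F]\*, [CycB],
  [Cdk1], [APC]\*): chains the G1/S (E2F, `K_cyc,e2f = 120 nM`), G2/M
  (Cdk1) and M-exit (APC/C) switches, with basal (APC-independent) cyclin
  degradation offsets δ_d = δ_b = 0.05. Table defaults
  (`d_syn = 0.15 nM/min`, `d_deg = 0.009/min`, `b_syn = 0.03 nM/min`,
  `b_deg = 0.003/min`, all α = 5, all ε = 0.01 min) yield regular
  oscillations with a ≈ 23.5 h period that visit G1, S/G2 and M in order.
* **Mass-action PP2A–ENSA–GWL oscillator**: the double-negative
  GWL/PP2A feedback with explicit complex formation and conservation of the
  GWL, PP2A and ENSA pools (eliminated algebraically), driven by Cdk1
  synthesis/degradation. Kinetic constants are the screened defaults that
  center the S-shaped APC/C response near [Cdk1] ≈ 20 nM; `b_syn`/`b_deg`
  have no published defaults and are required inputs. A `rate_divisor`
  uniformly divides the eight kinetic constants (not synthesis/degradation)
  to reduce timescale separation; the oscillator still runs at divisor 16.5.

**Parameter schedules** are piecewise-constant windows `[t_start, t_end)`
on named parameters (set or multiply), non-overlapping per parameter; the
integrator restarts at window boundaries. Ramps are not supported — every
perturbation modeled here is a step.

## Numerics

* **ODE integration**: SciPy `solve_ivp`; LSODA by default (about an order
  of magnitude faster than Radau on these systems at equal accuracy, as the
  problems are stiff only near the switching fronts), Radau/BDF available.
  Default tolerances rtol 1e−8 / atol 1e−10; long scenario runs use 1e−6 /
  1e−9. Output on a uniform grid.
* **DDE integration**: no delay-equation solver is part of the scientific
  stack used here, so the package carries its own: fixed-step classical
  RK4 whose history term interpolates the stored solution with cubic
  Hermite segments (third-order accurate overall, adequate because
  accuracy is dominated by the switching fronts). For t before the start,
  the lagged state equals the initial condition (constant history). The
  step defaults to min(ε/5, τ_min/4); when a state-dependent delay
  transiently drops below the step, the history is extrapolated linearly
  from the newest node. Stability is unproblematic: the fastest rate is
  1/ε and h ≤ ε/5 sits well inside the RK4 stability region.
* **Steady states**: multi-start `scipy.optimize.root` (Powell hybrid) from
  a level grid over the state box, seeded random starts, plus — for the
  embryonic systems — starts placed *on* the switch response curve, where
  all equilibria of these models necessarily lie (nearby equilibria at
  larger widths are otherwise easy to miss). Duplicates merge at 1e−6
  relative; stability from central-difference Jacobian eigenvalues, with
  "stable" meaning all real parts < −1e−8 and a marginal band of ±1e−8.
  For delayed systems equilibria are those of the τ = 0 reduction (delays
  do not move them); stability then refers to that reduction, a documented
  limitation — delayed-system regimes are classified by simulation.
* **Continuation**: secant-predictor pseudo-arclength with a Newton
  corrector on the augmented system, states and the clamped input
  normalized by their scales, adaptive step in [1e−4, 1e−1] (normalized),
  folds detected as sign changes of the input direction along the arc.
  Step underflow returns the partial curve with a truncation flag.
* **Oscillation metrics**: discard the first 50% of the span as transient
  (runs are sized for ≥ 10 nominal periods); find interior extrema;
  *sustained* requires ≥ 5 post-transient maxima, relative peak-height
  spread < 1% and mean peak-to-trough amplitude ≥ 1% of the variable's
  observed range (this is what filters damped and small-amplitude
  oscillations); *regular* means the CV of inter-maximum intervals is
  < 5%. The cut-offs are configurable; these defaults are the package's
  own choice, since only the filters themselves, not their numbers, are
  prescribed by the modeling protocol.
* **Regime labels**: Osc / Bi / MonoLow / MonoTop / Irregular combine
  equilibrium counting with probe simulations from a low and a high corner.
  Mono sides compare the equilibrium's switch-output coordinate with the
  fold outputs of the S-curve; a coexisting limit cycle and stable
  equilibria yield the composite label "Bi+Osc" rather than a guess.
* **Phase segmentation**: M wherever [APC]\* > 0.95; S/G2 wherever
  [E2F]\* > 0.95 and [APC]\* ≤ 0.95; G1 otherwise (ties resolve away from
  M and S/G2). Cycles are delimited by M→G1 transitions; per-cycle phase
  durations sum to the period up to one output step.

## Scenarios

* **Restriction point**: reduce `d_syn` tenfold inside a window. The
  default window starts mid-S/G2 (midpoint between E2F activation and the
  following APC/C activation): commitment is only effective once [CycD]
  has overshot the E2F *inactivation* threshold far enough that E2F stays
  on until mitotic entry — a reduction placed exactly at the activation
  knee lets [CycD] fall straight back and aborts the round. Completion
  means [APC]\* still reaches its M-phase level in the started cycle.
* **DNA damage in G1**: multiply δ_d by 3 inside the window. Interphase
  elongation is the shift of the APC/C activation onset that ends the
  perturbed cycle, relative to baseline.
* **DNA damage in G2**: set α_cdk = 30 inside the window (chosen so the
  standard model's [CycB] steady state sits below the shifted Cdk1
  activation threshold). Reported: elongation as above, plus [CycB] at
  M-phase onset ("mitotic CycB").
* **Circadian forcing**: α\*_cdk(t) = α_cdk + A + A·sin(ω t + φ), a
  Wee1-mediated, clock-driven shift of the mitotic-entry threshold,
  oscillating between the basal bend and α_cdk + 2A. φ defaults to 0 and
  is exposed because nothing pins it down. A = 0 reduces exactly to the
  autonomous model.
* **Locking detection**: on the post-transient [Cdk1] series (uniform
  grid), the normalized RMS mismatch between the series and time-shifted
  copies of itself is scanned over shifts from 0.5 to 5.4 forcing periods;
  the repeat period is the smallest local minimum below 1e−2 (normalized),
  refined parabolically. The repeat must span an integer q ≤ 5 of forcing
  cycles within 2% and contain an integer p ≤ 5 of [Cdk1] peaks
  (prominence 20% of the signal range); the forced cell-cycle period is
  repeat/p. Tolerances are configurable; these defaults are the package's
  choice.
* **Natural-period tuning**: the unforced period is adjusted to a target by
  a secant search on `d_syn` (all else at table defaults) to 1% relative.
  `d_syn` is the model's primary period knob — it sets the G1 duration —
  and tuning it leaves the switch geometry untouched. Each period
  evaluation simulates 12 nominal cycles and discards half.
* **Arnold maps**: a grid over (ω_cdk/ω_circadian, A) where each cell runs
  the forced model for 40 forcing periods and applies the locking detector;
  cells where the unforced model does not oscillate are marked
  not-applicable, and per-cell failures are recorded in the grid.

## Problem sizes

Chosen as the package's defaults: locking runs use 40 forcing periods with
half discarded as transient and ~8000 output samples; period tuning uses 12
cycles per secant step; the regime map in the test suite is a 6×7
(width × c) grid with 60-time-unit probes; delay maps use 3×3 grids of
80-time-unit delayed runs; fold-width oracles scan 10⁶ grid points.

## The synthetic-data generator

`interface.make_fixture` produces the only "data" the package ever sees:

* response curves sampled from a *known* scaling function (optionally with
  seeded multiplicative input noise, 1% in the recovery tests) — the ground
  truth for ξ fitting;
* periodic, damped (5%/cycle default), quasiperiodic (period ratio √2) and
  sawtooth series with known periods — the ground truth for the extremum
  metrics and the locking detector.

Identical spec + seed is bit-identical. These fixtures emulate clean
steady-state measurements and clean oscillation traces; they contain no
measurement noise models beyond i.i.d. Gaussian, no missing samples, no
drift. Passing the recovery tests therefore shows the estimators are
consistent on well-behaved input, not that they are robust to the artifacts
of real time-lapse or titration data.

## Known limitations

* Stability analysis of delayed systems is by simulation only (no
  characteristic-root analysis).
* The piecewise-linear ξ can approximate a smooth cubic's fold positions
  only to within a few percent — model mismatch, not an optimizer issue.
* The ξ fit minimizes input-axis least squares from a moment-based start
  with a derivative-free local search; the original fits of this kind were
  manual, so the objective is a documented choice, and no global search is
  attempted.
* Clock→cycle coupling is unidirectional and purely sinusoidal; the
  circadian oscillator itself is not modeled.
* No stochastic dynamics, no spatial variants, no fourth (FoxM1/CycA)
  switch.
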