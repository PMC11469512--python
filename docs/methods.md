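# Methods

This note documents the models, estimators and numerical choices behind
`headtrack`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic validation does and does not
establish.

## The paradigm being emulated

A participant experiences optic flow from simulated self-motion through a
plane of plants and continuously reports the perceived heading with a
joystick, recorded at 90 Hz. Heading follows a bounded random walk; a 2×2
within-participant design crosses self-motion **speed** (SLOW 0.4–0.6 m/s,
FAST 2–3 m/s) with plant **density** (SPARSE 100 vs DENSE 5,000 plants in
10,000 m²). More informative optic flow (faster, denser) is expected to
produce faster and less variable heading responses and a smaller fitted
sensory-noise parameter.

## Stimulus generator (`headtrack.stimulus`)

Every 200 ms a heading change δ ~ N(0, 20²) deg is drawn; the candidate
heading is h + δ. If the end-of-step position would leave a circular
boundary, the step is taken at h + δ + 180 instead (flagged `reflected`); a
second failure raises rather than looping — with the default 50 m radius
and the design speed ranges this is practically unreachable, and a loud
error beats silently re-drawing. Speed is redrawn uniformly per 200 ms step
(the underlying experiment states the range but not the distribution;
uniform is the least-commitment choice). Coordinates: top-down plane,
heading clockwise from −y, so the starting heading 180° points +y
("forwards"). The boundary radius defaults to 50 m, consistent with the
10,000 m² arena.

Plant fields are placed by rejection sampling with a spatial hash grid and
a bounded attempt budget. One deliberate deviation: 100 plants with 15 m
minimum separation cannot exist in 10,000 m² (the hexagonal packing bound
is ≈51 points), so the SPARSE default keeps the density that defines the
condition (100 plants) with a feasible 5 m anti-clumping distance; the 15 m
rule is honoured — and unit-tested — at counts where it is geometrically
possible. Plant fields are written for completeness but feed no analysis
stage (density acts only through the real experiment's optics).

## Synthetic observers (`headtrack.observer`)

The simulated participant is the steady-state Kalman tracker described
below, running on the same 200 ms grid as the stimulus (the grid on which
the process variance Q is defined), plus two response-stage components:

* a **response lag**: the joystick trace is the internal estimate delayed by
  `lag_s` (zero-order held at the frame rate);
* **motor noise**: white N(0, motor_sd²) per frame added after the lag (an
  optional first-order low-pass mimics joystick inertia; off by default —
  the simplest motor model first, since the analyses under test do not model
  the motor stage either).

Default ground-truth parameters per condition follow the effect pattern the
paradigm is designed to detect: response lags 1.18/1.01/0.86/0.69 s and
sensory-noise SDs 25/21/18/15 deg for SLOW·SPARSE / SLOW·DENSE /
FAST·SPARSE / FAST·DENSE, motor SD 8 deg everywhere. The lag values mirror
the reference cell and contrast magnitudes typical for this paradigm; the
noise SDs sit above classical heading-discrimination thresholds, as fits to
continuous-tracking data do (motor variability is absorbed into R there).
Two jitter layers make datasets realistic for mixed models: per-participant
jitter (lognormal on R, additive normal on lag, shared across a
participant's four conditions) provides genuine random effects, and
run-level jitter (independent per recording) emulates the large
within-participant, run-to-run variability continuous tracking shows —
without it, within-participant contrasts would be artificially noise-free.
The pipeline defaults set both layers to σ_log = 0.15 on R and 0.08 s on
the lag.

Sub-seeds for every trajectory and observer derive from the master seed via
`SeedSequence([master_seed, counter])`, so any stage can be regenerated
independently and identical configurations are byte-reproducible.

## Cross-correlogram analysis (`headtrack.ccg`)

The lag grid is specified in seconds (0–3 s in 0.05 s) and realized as the
nearest whole frame offsets at the recording's own frame rate, reproducing
~50 ms spacing at any rate. For each lag, the mean absolute circular
difference between the lag-shifted stimulus and the response is taken over
the frames that exist (no padding). Normalization divides the curve by its
own maximum, so the normalized least error is a within-recording ratio in
(0, 1]. Ties at the minimum break toward the smaller lag — this matters
only for degenerate (e.g. exactly flat) profiles, where the tie-break sends
non-trackers to lag 0 and thence into the border exclusion. Exclusion is per
participant: one border valley in any condition removes all four recordings.

The analysis runs on the heading angle itself, not its temporal derivative:
the stimulus only changes every 200 ms, so a derivative analysis would have
to collapse 12-frame windows and lose most of the frame-level data.

## Kalman observer model and the sensory-noise fit (`headtrack.kalman`)

For a random walk with step variance Q observed with noise variance R, the
steady-state posterior variance is the positive Riccati root

    P = (Q/2)·(√(1 + 4R/Q) − 1),   K = (Q + P)/(Q + P + R),

and the update is x̂ₜ = x̂ₜ₋₁ + K·∠(yₜ, x̂ₜ₋₁), with ∠ the signed circular
difference. K → 1 as R → 0 and decreases monotonically in R.

Fitting runs on the 200 ms step grid after shifting the response back by
the response lag (fixed 1 s by default; the pipeline substitutes each
recording's own CCG lag, which protects the fit from lag mismatch when
conditions differ in responsiveness). The default likelihood is the
generative model's own one-step decomposition: writing dₜ = ∠(yₜ, x̂ₜ₋₁)
for the prediction error against the *presented* heading and
Δₜ = ∠(x̂ₜ, x̂ₜ₋₁) for the observed response change,

    Δₜ = K·dₜ + K·εₜ,   εₜ ~ N(0, R),

so the innovation residual eₜ(R) = Δₜ − K(R)·dₜ is N(0, K²R), and R enters
through both K and the residual scale (`variance_model="innovation"`).
This is a correctly specified MLE on simulated observers: median relative
recovery error ≈5 % on single 90 s runs at R = 100 deg². Two alternative
scalings sometimes written for this residual class are retained or
documented deliberately:

* `variance_model="paper_literal"` uses the residual K·∠(x̂ₜ₋₁, yₜ) with
  standard deviation K²/R, exactly as printed in the tracking literature
  this fit descends from. The form is dimensionally inconsistent (units of
  1/deg) and collapses to the R lower bound on simulated data; it exists
  for audit, never as a default.
* Modelling that same residual with its true generative variance — which is
  K²(P+Q), not K²(P+Q+R), since the lag-corrected response carries the
  posterior error (variance P) and the stimulus takes one further Q-step —
  is consistent but far less efficient (the variance-to-R mapping is steep);
  it fails 25 %-level recovery on single runs, which is why the innovation
  form is the estimator of record. `residual_series` exposes the residual
  itself, with its K²(P+Q) variance stated and tested.

The optimizer works on log R: a 41-point log-spaced scan over
[10⁻⁶, 10⁶] deg² locates the basin and bounded scalar minimization refines
it; estimates pinned at a bound are flagged (`bounds_hit`) rather than
hidden — perfectly tracked data legitimately pin R at the lower bound.

## Population statistics (`headtrack.popstats`)

All three procedures share the fixed-effect structure
`dv ~ Speed + Density` with by-participant random intercepts and slopes,
treatment-coded with SLOW and SPARSE as reference levels: the intercept
estimates the SLOW·SPARSE cell mean and both difference contrasts are
negative when FAST/DENSE improve performance. Fits walk a simplification
ladder — correlated random slopes, uncorrelated slopes, intercept only —
falling through only on non-convergence, and record the rung used. A
constant dependent variable (common for the grid-valued lag DV under null
conditions) is handled exactly: intercept = the constant, zero contrasts,
zero width.

The subsampling bootstrap re-runs the *entire* CCG analysis per repetition
on half the participants and, independently per recording, 25 % of the
frames (both without replacement), refits the mixed model, and collects the
two contrasts; percentile 2.5/97.5 bounds form the CI. Half-sampling
without replacement is variance-calibrated at the participant level — the
variance of a half-sample mean about the full-sample mean, σ²(1/m − 1/n)
with m = n/2, equals the σ²/n sampling variance of the full-data mean — so
no m-out-of-n rescaling is applied. Repetitions whose model fails are
dropped and counted; more than 10 % failures aborts the run. The frame-level
model uses the per-frame absolute error at each recording's best lag as DV
with the same structure, and reports Wald 95 % CIs from the REML fit (a
parametric interval; the heavy manual bootstrap is reserved for the
lag-bearing analysis where it is the only option).

Mixed models are fit by an internal profiled-REML solver
(`headtrack._lmm`): the scaled random-effects covariance is parameterized
by an unconstrained Cholesky factor (boundary cases reachable), the
residual variance is profiled analytically, and the criterion is evaluated
from per-group cross-products with batched linear algebra — a fit costs
~2–5 ms regardless of row count, which is what makes bootstrap studies with
tens of thousands of refits tractable on one CPU. The solver is verified
against statsmodels' MixedLM (estimates to ~1e-6, standard errors to
~1e-4) in the test suite; statsmodels remains the independent reference
implementation, not the inner loop.

## Validation studies and their scales

The acceptance suite (`tests/test_acceptance.py`) validates, end to end:

1. generator statistics — pooled non-reflected step SD within 2 % of 20°
   over 25 seeded runs; speed bands; plant spacing; DENSE count;
2. the Kalman closed forms against the Riccati equation and limit cases;
3. pure-delay lag recovery — exact with no noise, within one grid step in
   ≥95/100 seeds at 10° motor noise;
4. sensory-noise recovery — median relative error ≤25 % over 50 runs at
   R = 100 deg², and correct R ordering in ≥95/100 pairs at 50 vs 400 deg²;
5. bootstrap calibration — null-fixture CIs cover zero in 90–99 % of 50
   syntheses (200 repetitions each) at the study's post-exclusion sample
   size of 28 participants, and both contrasts are detected (negative, CI
   excluding 0) on fixtures carrying the design's effect pattern;
6. byte-identical reruns of the full pipeline at a fixed seed.

The null-coverage study uses n = 28 because the percentile CI's small-sample
behaviour is a property of the method, not the implementation: at very
small n (e.g. 6 participants) the contrast's between-participant variance
is estimated from too few degrees of freedom and the normalized-error CIs
genuinely under-cover, while the grid-valued lag DV degenerates toward a
constant and its CIs trivially over-cover. At the study's own scale both
effects are minor. Two features of the null fixture are essential and
deliberate: the stimulus process is identical across conditions (one speed
range everywhere — with condition-specific speeds, boundary reflections
alone shift the normalized error between speed conditions, so the fixture
would not be null; the experiment randomized trajectories across conditions
for the same reason), and both jitter layers are on (shared-only jitter
cancels in within-participant contrasts, leaving the null contrast with no
genuine variance for the CI to be calibrated against).

## What the synthetic validation does not show

The generator emulates the stimulus exactly but the participant only
schematically: real joystick control is autocorrelated and nonstationary,
real lags drift within a run, and eye movements, training effects and
attention lapses are absent. Passing recovery tests therefore certifies the
estimators under the stated observer model — not that human data satisfy
that model. The Kalman fit in particular absorbs unmodelled motor
variability into R̂ (inflating it relative to perceptual-only noise), which
is also the standing caveat for the paradigm itself.
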