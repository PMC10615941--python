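# Methods

This package simulates and refits two evidence-accumulation models of
two-choice response times to study a fitting artefact: when each of two
within-subject conditions is fitted separately, the per-participant
hard-minus-easy *difference scores* of boundary separation (`a`) and
non-decision time (`t0`) correlate strongly negatively across participants
even when no participant truly differs between conditions.  This note
documents the models, the estimators, the synthetic populations, the
numerical choices, and what the desk-scale runs can and cannot show.

## The drift-diffusion model (DDM)

A decision is a Wiener process with drift `v` and diffusion coefficient
`s`, started at `z = zr * a` between absorbing boundaries at `0` (error)
and `a` (correct), with the observed RT equal to the first-passage time
plus a non-decision offset `t0`.  Throughout the package:

* `s = 1` (the unit-diffusion convention), so parameter ranges such as `v`
  in [0, 4] are used verbatim; an estimator computed under another scaling
  converts before reporting.
* `zr = 0.5` (unbiased start) and all inter-trial variability parameters
  are zero.  These are fixed, not fitted.
* Accuracy coding: the upper boundary codes the correct response.  With
  `zr = 0.5` the process is symmetric, so which boundary carries which
  label is pure bookkeeping.

### First-passage density

`wiener_fpt_density` evaluates the defective first-passage density at
either boundary with the dual series representation of Navarro & Fuss
(2009): a small-time expansion (Gaussian image terms in `(w + 2k)`) and a
large-time expansion (sine series with Gaussian decay), each with a
closed-form bound on the number of terms needed for a target absolute
tolerance on the normalized scale; per time point the cheaper expansion is
used.  The truncation target is 1e-7.  Correctness is checked by adaptive
quadrature: upper plus lower densities integrate to 1 within 1e-6 across a
grid of `(v, a, zr)`, the upper mass alone matches the closed-form
absorption probability, and the zero-drift case reproduces `P(upper) = zr`
and mean decision time `z(a - z)/s^2`.

### Trial simulation

The default simulator inverts the defective CDFs: for a parameter set it
tabulates both boundary densities on a 4096-point grid (cumulative
trapezoid), choosing the horizon as `6 a^2` normalized time units and
doubling it until all but 1e-8 of the mass is captured, then samples the
boundary from the total masses and the decision time by inverse
interpolation.  The horizon tracks the natural `a^2` time scale because a
fixed floor would place the entire FPT spike of a very small `a` between
the first two grid points.  Grids are memoized per parameter set, which
halves the work in the no-difference designs where both conditions share
parameters.  An Euler–Maruyama path simulator (step <= 0.5 ms) is provided
as an independent cross-check; the two agree in distribution and the
inverse-CDF route matches the density to Kolmogorov–Smirnov D < 0.01 at
n = 50,000.

### Maximum-likelihood fitting

`fit_ddm_ml` maximizes the summed log defective density over `(v, a, t0)`
per condition by bounded Nelder–Mead simplex, with bounds `v` in [-10, 10],
`a` in [0.05, 5] and `t0` in [1e-4, min RT - 1 ms]; the t0 cap prevents
degenerate likelihoods in which trials fall below the non-decision time.
Per-trial densities are floored at 1e-10 so misfit regions stay finite;
trials with `rt <= t0` contribute the floor rather than raising, so the
simplex can recover from bad proposals.  Starting values come from the EZ
closed form on the condition's summary statistics, followed by two
10%-jittered restarts (three simplex runs in total); convergence tolerances
are 1e-3 on parameters and log-likelihood.  Tightening the tolerances to
1e-5/1e-7 and re-polishing changes fitted log-likelihoods by < 1e-3 in the
median and leaves the difference-score correlations unchanged at the third
decimal, so the optimizer is not a noise source at the scales studied.

With both conditions free the joint likelihood separates and each condition
is fitted independently; under a sharing constraint (e.g. drift equal
across conditions) the pooled likelihood is maximized jointly, with shared
starts averaged across conditions.

### EZ-diffusion closed form

`fit_ez` inverts (proportion correct, variance and mean of correct RTs)
into `(v, a, t0)` with the published method-of-moments equations
(Wagenmakers, van der Maas & Grasman, 2007), computed directly on the
`s = 1` scale (the equations are scale-covariant).  Accuracies of exactly
0, 0.5 or 1 are edge-corrected by `1/(2n)` before the logit — the
correction rule is a package choice, documented rather than inherited.

## The Linear Ballistic Accumulator (LBA)

Two independent linear accumulators race to threshold `b`; per trial each
draws a start point uniform on `[0, A]` and a drift from a Normal with SD
`s` around its mean — `v` for the correct accumulator and `1 - v` for the
error accumulator.  Response caution, the analogue of boundary separation,
is `b - A/2`.  The defective density of a response is the winner's
finishing-time density times the loser's survivor function (closed form for
the Uniform-start × Normal-drift race), renormalized by
`1 - P(both drifts <= 0)`; the simulator redraws exactly those trials, so
simulation and likelihood describe the same process.

The drift SD is fixed at `s = 0.3` in generation and fitting, cohering with
the starting heuristic that reads the initial drift off the Normal quantile
function with SD 0.3; `s` is a scaling constant of the model, not an
estimable parameter here.  Because this choice is a convention, the suite
includes a sensitivity check that regenerates and refits a population at
`s = 1` and confirms the caution-diff/t0-diff correlation remains below
-0.5 — the artefact is not an artifact of the scaling choice.

Fitting uses bounded L-BFGS-B on `(v, A, delta, t0)` with `b = A + delta`,
`delta > 0`, so `b > A` holds everywhere in the search; starts follow the
standard heuristics (t0 at 90% of the fastest RT; drift from the accuracy
quantile; `A` twice the RT inter-quartile range; `b = 1.25 A`), with
jittered restarts on failure.

## Synthetic populations

* **No-difference (DDM)**: per participant one draw of `v ~ U[0, 4]`,
  `a ~ U[0.5, 2]`, `t0 ~ U[0.2, 0.5]`, used bit-identically in both
  conditions.  Grand means of the simulated behaviour: RT ~0.625 s,
  accuracy ~84.6%.
* **Manipulated**: the chosen parameter is drawn per participant as an
  (easy, hard) bivariate-Normal pair with correlation 0.5 and
  condition-specific means/SDs implying a standardized difference of 0.3,
  0.5 or 0.8 (drift 2.3/2.5/2.8 vs 2.0, SD 1; boundary 1.25 vs
  1.37/1.45/1.57, SD 0.4; non-decision 0.350 vs 0.385/0.400/0.430, SD 0.1);
  the other parameters are uniform draws copied across conditions.
  Positivity is enforced by rejecting and redrawing whole pairs (cap 1000
  per participant), which preserves the correlation structure, unlike
  truncation or clipping.  An all-three variant draws each parameter as its
  own independent pair.
* **Correlated differences**: easy-condition parameters as in the
  no-difference design; the hard condition adds a zero-mean bivariate-Normal
  `(a_diff, t0_diff)` with SDs 0.1 and 0.05 and correlation ±0.7 (drift
  unchanged).  Mean differences are zero by construction.
* **No-difference (LBA)**: `v ~ U[1, 4]`, `A ~ U[0.5, 2]`,
  `b ~ U[A + 0.001, 2]`, `t0 ~ U[0.2, 0.5]`, copied across conditions.
  `A` is redrawn in the ~0.07%-probability sliver above 1.999 where the `b`
  interval would be empty.

One study seed expands into per-participant child seeds
(`numpy.random.SeedSequence.spawn`), so enlarging a population extends it
without reshuffling existing participants, and identical configurations
reproduce every output byte for byte.

## Difference scores and correlations

Difference scores are hard minus easy, per participant and parameter;
participants with a missing condition or an unconverged fit in either
condition are dropped listwise (with a count in the run log).  The readout
is the 9 × 9 Pearson matrix over {a, v, t0} × {easy, hard, diff} (caution
replacing `a` for the LBA), with |r| = 0.1/0.3/0.5 attached as small/
medium/large effect-size markers.  Zero-variance columns propagate as
missing values, never as zero.  The outlier-robustness check standardizes
the two variables being correlated and removes cases with |z| > 2.5 on
either before recomputing r; standardization is applied within the pair
(whether the original analyses standardized all nine columns jointly is
ambiguous; pairwise is this package's choice).

## Model competition

Eight models form the boolean cube over whether `v`, `a`, `t0` may vary
across conditions (3 to 6 free parameters).  Per participant and model the
constrained ML fit maximizes the pooled likelihood; per model,
`AIC = 2k - 2LL` and `BIC = k ln(n) - 2LL` (with `n` the participant's
pooled trial count — the BIC sample-size convention is a package choice)
are summed over participants, and Akaike weights
`w_i = exp(-Δ_i/2) / Σ exp(-Δ_j/2)` are computed from the summed AIC and
BIC.  Group-level selection by summed criteria is the default; the
per-participant criterion table is retained for participant-level
selection, since a model superior at the group level need not be superior
for everyone.

Nested models are guaranteed never to outscore their super-models: every
constrained fit starts both from the fully free solution (projected by
averaging shared parameters) and from the fully shared solution (embedded),
and a final repair pass adopts a nested optimum outright if an optimizer
run for a super-model lands below it (the embedding attains the identical
likelihood, so the invariant holds by construction).

## Problem sizes

The full designs use 1000 participants × 1000 trials per condition.  The
test suite and the acceptance script run the same code paths at sizes
chosen so each quantity's Monte-Carlo error is small against the tolerance
it is compared at:

* behavioural grand means: 1000 participants × 300 trials (simulation only;
  SE of the grand mean RT ≈ 0.007 s);
* parameter recovery and the ML/EZ difference-score correlations: 200
  participants × 1000 trials — the trial count is kept at the full design's
  value because both the recovery ceiling and the size of the spurious
  correlation depend on per-participant estimation noise, which scales with
  trials, not participants;
* manipulated-parameter cells: 300 × 1000 for the drift cell (where the
  artefact's size is compared), 150 × 500 for the cells where it is absent;
* correlated-difference designs: 300–500 participants × 1000 trials (the
  attenuation of a true +0.7 correlation is noise-driven, so trials must
  match the full design);
* LBA: 200 × 500; model competition: 100 × 500.

## Known limitations

* The generators emulate the stylized populations above, not empirical
  data: no inter-trial variability parameters, no contaminant RTs, no
  response bias, equal trial counts everywhere.  Passing tests show the
  artefact and its remedies for the pure models; effect sizes in real data
  with variability parameters or contaminants may differ.
* EZ requires two response categories to be informative; perfect-accuracy
  conditions rely on the edge correction.
* The LBA's `A` and `b` are weakly identified separately when accuracy is
  near ceiling; their combination `b - A/2` (caution) is the stable
  quantity, which is why caution, not `b`, is analysed.
* The correlation estimates at desk scale carry sampling error of roughly
  `(1 - r^2)/sqrt(n)`; at 200–300 participants that is ±0.02–0.04 for the
  large correlations studied here.
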