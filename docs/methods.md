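# Methods

## The model family

A lifespan curve records percent survival `N(t)` of a cohort against days
of adulthood, rescaled so `N0 = 100 %` and never fitted. The bilogistic
models treat the cohort as a mixture of two subpopulations:

* a fraction `f` following a logistic survival term with median `t1`,
* the remainder `1 − f` with median `t2`,

each term normalized by its `1 + e^{−k·tᵢ}` factor so the curve starts at
exactly `N0` at day 0. Bilogistic 1kf shares a single death rate `k`
across phases (4 parameters); Bilogistic 2kf gives each phase its own rate
(5); Bilogistic 2k fixes `f = 0.5` with two rates (4). The 2kf model
contains the other two as limit cases and reduces to Whiting–Buchanan when
`t1 = t2`. `reduce_model` performs these reductions and refuses them when
the limit condition is violated beyond tolerance (relative 1e−9).

The six comparator models (Whiting–Buchanan, Gompertz–Makeham, Logistic,
Wilson, Weibull, Gompertz) are implemented exactly as their survival
formulas are conventionally printed. Two conventions matter:

* the Logistic model's denominator parameter is a **time scale** (days),
  stored as `logistic_scale` to avoid collision with the bilogistic death
  rate `k` (day⁻¹); the Logistic is also the one model that does not pass
  exactly through 100 % at t = 0;
* the Wilson model's `k` is a dimensionless steepness exponent, not a
  rate, and carries wider bounds.

### Parameter conventions

Phase labels are interchangeable (`(f, k1, t1) ↔ (1−f, k2, t2)` leaves the
curve unchanged), so `validate_params` canonicalizes every set to
`t1 ≤ t2`, making fitted parameters comparable across replicates.
Default bounds are a generous envelope for worm/fly assays: rates
(1e−4, 10] day⁻¹, times (0.1, 200] days, `f ∈ [0, 1]`, shape exponents
(0.01, 100], Makeham term (1e−6, 10]. Exponentials are evaluated in
log-space (`logaddexp`) or with clipped exponents so every model stays
finite for `k·t` up to 700 and beyond.

A three-parameter "Bilogistic 1k" (eq. (2.1)'s form with `f` fixed at 0.5
and a single rate) is sometimes discussed as a further simplification; it
is not in the catalogue — fix `f` at fitting time if needed.

## Fitting

**Least squares.** The objective is the sum of squared differences between
observed and predicted percent survival at the recorded scoring days (one
point per day, including day 0 at 100 %). Bounds are enforced through a
smooth scaled-logit transform of every parameter, so the optimizer —
SciPy's trust-region reflective `least_squares` — works unconstrained.
Fits are multi-start: a deterministic heuristic initialization plus eight
perturbed starts drawn uniformly in the transformed space (roughly
log-uniform multiplicative jitter) from a stored seed; the lowest-SSE
solution wins, ties broken by first found. Identical inputs and seed give
bit-identical results.

The initialization reads start values off the curve: `t1`/`t2` from the
first crossings of 75 % and 25 % survival, `tlag` from the 50 % crossing
(falling back to span fractions when a quantile is never reached), rates
from the steepest observed per-day decline divided by 25 (a logistic phase
declines at `k·N0/4 ≈ 25k` %/day at its midpoint), `f = 0.5`. A constant
curve, or one with fewer points than parameters, is refused as degenerate.

**Maximum likelihood.** The observation model is independent Gaussian
error on the percent values with a common unknown scale σ, profiled out
analytically: `σ̂² = SSE/m`, `ln L = −m/2·[ln(2π σ̂²) + 1]`, floored at
`σ ≥ 1e−8` so noise-free curves keep a finite likelihood. This makes the
MLE shape estimates coincide with least squares — by design, since the
least-squares solution is included among the MLE starts before the final
polish (Nelder–Mead simplex by default; bounded L-BFGS-B for the Gompertz
and Gompertz–Makeham models, whose double-exponential surface the simplex
handles less well). An interval-censored multinomial likelihood on the
death counts would weight the curve points by their actual binomial
information; it is noted as the principled alternative but is not
implemented — see Limitations.

**Information criteria.** `AIC = 2k − 2 ln L` and
`AICc = AIC + (2k² + 2k)/(m − k − 1)` with `k` counting only the model's
shape parameters (4 for 1kf, 2 for the Logistic, ...), not σ — matching
the conventional printed parameter counts for these models. The adjusted
RMSE is `√(SSE/(m − k))`. Both are undefined (raised, or NaN on the
`FitResult`) when `m` is too small for the denominator.

## Model comparison

`compare_models` fits every (replicate, model) pair by both routes and
tabulates AICc (from the MLE fit) and adjusted RMSE (from the
least-squares fit). Per replicate and criterion the best model is counted;
differences below 1e−9 are reported as shared ties rather than arbitrated.
Failed cells are marked missing and logged; the comparison proceeds.

Residual binning pools (day, residual) pairs into half-open bins
`[start, start + width)` anchored at day 0, width 2, 3 or 4 days. With two
or more replicates the bin's s.e.m. is the standard deviation of the
replicate-level bin means over √(number of replicates); with a single
replicate it falls back to the within-bin s.e.m. of the pooled residuals,
flagged `single_replicate`. Empty bins inside the observed range are
emitted with count 0, so counts always sum to the pooled total.

## Non-parametric baseline

Kaplan–Meier estimation and the log-rank (Mantel–Cox) test are delegated
to `lifelines`; the module owns the conventions. Deaths are processed
before censorings at tied times (the standard convention). Curves for
fitting are evaluated at every scored day, including days with no deaths;
no interpolation is performed for unscored days. Live animals at assay end
must be recorded as censored at their last observation — `alive` is not a
valid row status. A log-rank between groups without deaths on both sides
is refused as undefined; p < 0.05 is exposed as a convenience flag.

## The simulator

The bilogistic curve has an exact generative reading: phase membership is
Bernoulli(`f`), and each phase's death time is logistic with location `tᵢ`
and scale `1/kᵢ`, conditioned on `T > 0` — the normalizing numerator of
the survival formula is precisely this truncation. Sampling inverts the
conditional CDF in closed form (`t = tᵢ + ln[(1 + e^{−k tᵢ})/u − 1]/k`),
exact and O(1) per draw, so the population mean of "alive at t" reproduces
the closed-form curve to binomial error.

Defaults emulate a daily-scored nematode assay: 100 individuals per
replicate, daily-rounded scoring (death times rounded **up** to whole
days, mimicking discovery at the next scoring visit), no censoring.
Optional censoring is geometric per day, independent of phase, with
deaths winning ties — the simplest right-censoring mechanism; real
censoring causes (contamination, lost animals) are not modelled.
Replicates draw from sub-seeds spawned deterministically from the master
seed. Note that a Kaplan–Meier curve built from ceiling-rounded times and
evaluated at whole days is an unbiased estimate of the continuous truth at
those days (`⌈T⌉ > d ⟺ T > d` for integer `d`), so daily scoring does not
bias parameter recovery at the integer grid.

What the simulator does **not** emulate: batch effects between replicates
(sub-seeds give pure sampling variation), informative censoring,
plate/vial structure, or measurement error in the scored day. Tests
passing on simulated data therefore demonstrate correctness of the
estimation machinery under the stated sampling model, not robustness to
those real-world artefacts.

## Cohort statistics

Each replicate contributes one fitted parameter vector; a group's summary
is the per-parameter mean and s.e.m. (sd/√n) over replicates, with
non-converged fits excluded, never imputed. Between-group comparison is a
one-way ANOVA across groups on one parameter followed by Tukey HSD, with
stars at p < 0.05/0.01/0.001/0.0001. A two-way design (e.g. group ×
batch) is deliberately not modelled — the replicate structure here has
only one factor. Groups with a single replicate are excluded with a
warning; identical values across all groups short-circuit to F = 0, p = 1
rather than a 0/0.

## Problem sizes and tolerances in the test suite

The suite exercises the pipeline at the scale of a real assay campaign:
15 replicates × 100 individuals for recovery and model-selection checks,
10⁵ individuals for generative-consistency checks (2 % sup-norm), 50
random truths for noise-free recovery (4-decimal agreement), 200×200
brute-force grids as optimizer oracles for all two-parameter models, and
300 null resamples for the ANOVA type-I-error check. Limit-case identities
are asserted to 1e−12 relative error on 600-point grids; the MLE/LS
equivalence to 1e−6 relative SSE.

## Known limitations

* **AICc is liberal toward biphasicness on staircase data.** Under the
  Gaussian-on-percent likelihood, `2Δln L = m·ln(SSE_a/SSE_b)`: at m ≈ 30
  curve points a ~18 % SSE reduction already outweighs the 1kf-vs-Logistic
  AICc penalty. Because KM points from ~100 individuals are strongly
  autocorrelated (a staircase, not iid noise) and a lone survivor holds
  the curve at 1 % for many days, the two extra bilogistic parameters
  reliably achieve such reductions even when the generating truth is a
  single phase — the suite's model-selection check computes exactly this
  on simulated monophasic replicates. Biphasic detection at this cohort
  size should therefore be corroborated by the binned-residual analysis
  and by replication, not read off AICc wins alone; an interval-censored
  multinomial likelihood would weight the points by their true information
  and is the natural extension.
* No per-fit confidence intervals; uncertainty is assessed across
  replicates (s.e.m., ANOVA).
* The Gaussian likelihood treats a 1 % misfit at the tail the same as at
  the shoulder, although the KM variance differs between them.
* Curves, not event times, are fitted: two assays with identical daily
  curves but different censoring patterns fit identically.
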