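# Methods

## Model and Bayes factor

Two independent groups of equal size `N` are modelled as
`y ~ N(μ_j, σ_j²)`, with a common within-group variance (t test) or
group-specific variances (Welch's test).  Hypotheses: `H0: μ1 = μ2`
against `H1: μ1 ≠ μ2` or `H2: μ1 > μ2`.

The approximate adjusted fractional Bayes factor is built from a normal
approximation to the posterior of `(μ1, μ2)` — means at the sample
means, diagonal covariance `σ̂_j²/n_j` with `σ̂²` the pooled unbiased
variance under the common-variance model — and a fractional prior that
re-uses a fraction `b_j = m/(2n_j)` of the data's information per group:
normal, centred at zero (the "adjusted" part: the prior sits on the null
boundary), per-mean variance `(1/b_j)·σ̂_j²/n_j = 2σ̂_j²/m`.  The
multiplier `m ∈ {1, 2, 3}` gives the `b`, `2b`, `3b` sensitivity ladder
of the minimal-training-sample idea (half an observation per group, one
per mean, one per mean plus half for the variance).

Because both distributions are bivariate normal with diagonal
covariance, the fit and complexity integrals are evaluated **exactly**
on the difference `δ = μ1 − μ2`, which is itself normal:

| quantity | value |
|---|---|
| posterior of δ | `N(ȳ1 − ȳ2, σ̂²(1/n1 + 1/n2))` (pooled) or `N(ȳ1 − ȳ2, s1²/n1 + s2²/n2)` |
| prior of δ | `N(0, 4σ̂²/m)` (pooled) or `N(0, 2(s1² + s2²)/m)` |
| `f0`, `c0` | posterior/prior density of δ at 0 (Savage–Dickey) |
| `f2`, `c2` | posterior/prior `P(δ > 0)`; `c2 = 0.5` exactly |
| `BF01` | `f0/c0`; `f1 = c1 = 1` for the unconstrained alternative |
| `BF02` | `BF01 / (f2/c2)` |

No Monte-Carlo integration enters the Bayes factor itself; the 2-D
sampling oracle appears only in the test suite as an independent check.
Exact consequences used as test invariants: `c0 ∝ √m`,
`BF_0alt(m) = BF_0alt(1)/√m`, and invariance of every BF under common
location shifts and positive rescalings of the data.

Unequal group sizes are supported in the BF computation by applying the
fraction per group (`b_j = m/(2n_j)`); the design search itself uses
equal per-group sizes.

## Numerical choices

All BF arithmetic is in log space: `log f2` uses the complementary
log-CDF (`norm.logsf`), so designs with `|z| > 8` (large `N`, large
effects) evaluate exactly where naive pdf/CDF products underflow.
`BFResult` exposes `log_bf_0alt` alongside `bf_0alt`; the exceedance
comparison `BF > threshold` is performed on the log scale.  Plain
`bf_0alt` may honestly overflow to `inf` (or underflow to 0) in extreme
cases; the reciprocal pair always multiplies to 1 within floating
tolerance.

Degenerate inputs are rejected: groups with fewer than two observations
or zero sample variance, non-positive population variances, `η ≤ 0.5`
(the criterion would be met by a coin flip), and one-sided designs whose
alternative population has `μ1 ≤ μ2` (the orientation must match `H2`).
Thresholds below 1 are accepted with a warning, since exploratory
designs legitimately use `BF_thresh = 1`.

## Simulation

The sample-size search needs only the per-dataset sufficient statistics,
so datasets are simulated directly on that scale: sample means are
`N(μ_j, σ_j²/n)` and unbiased variances are `σ_j²·χ²(n−1)/(n−1)`,
independent — the exact sampling distributions for normal data, not an
approximation.  This makes a full search (`T = 10,000` datasets per
population per candidate `N`) a sub-second computation.  A raw-data
path (`gen_raw`) is kept for data analysis and validation; the test
suite confirms by a Kolmogorov–Smirnov test that the two routes produce
indistinguishable BF distributions.

Reproducibility and coupling: child RNG streams are keyed by
`(master seed, candidate N, population)` via `numpy.random.SeedSequence`
spawn keys.  All prior fractions and both constraint probabilities at a
given `N` therefore see the *same* simulated datasets, so the `b/2b/3b`
sensitivity triple differs only through the prior, not through
Monte-Carlo noise.  Streams at different `N` are necessarily
independent (datasets have different sizes), which is why the returned
`N` can wobble by a few units between master seeds.

## Search

The design criterion is
`P(BF_0a > thresh | H0) ≥ η` and `P(BF_a0 > thresh | H_alt) ≥ η`,
with the null population taking both means equal to `μ2` and the
configured variances.  Starting from `N_start = 10`, the search doubles
`N` until the criterion passes (bracketing, cap `N_max = 10,000`), then
bisects the bracket treating the empirical exceedance probability as
monotone in `N`.  Cost is about `2·log2(N)` Monte-Carlo evaluations —
12 for answers near 100, up to ~18 near 1000 — instead of the hundreds
required by unit stepping.  If the criterion is unmet at `N_max` the
search raises an error carrying the probabilities achieved there.

The returned `N` satisfies both constraints on its own evaluation
streams and `N − 1` fails at least one of them whenever the bisection
pinned the boundary.  Because the empirical probabilities at
neighbouring `N` are estimated from independent streams, the minimal `N`
is identified up to Monte-Carlo noise: at `T = 10⁴` the probability SE
is ≈ 0.004 and the reported `N` may differ by a few units between seeds
(more where the exceedance curve is flat in `N`, e.g. small effects with
`BF_thresh = 1`).

## Frequentist baseline

For reference, `power_ttest`/`ssd_freq` compute exact two-sample t-test
power from the noncentral t distribution (`df = 2N − 2`, noncentrality
`d·√(N/2)`) and the exactly minimal `N` for a target power, reproducing
the classical 394/64/26 per group for `d = 0.2/0.5/0.8` at `α = .05`,
two-sided, power .80.  Welch-specific frequentist sample sizes are out
of scope.

## What the simulations do and do not show

The generator draws i.i.d. normal data with known population variances —
exactly the model under which the design criterion is defined.  Passing
tests therefore validate the Bayes factor arithmetic and the search
logic, not robustness to skewness, outliers, unequal group sizes in the
field, or misspecified effect sizes; a planned `d` smaller than the true
effect wastes resources and a larger one under-powers the design, just
as in classical power analysis.

## Design choices where the design was open

* **Sufficient-statistic simulation by default.**  Statistically exact
  and two orders of magnitude faster than raw data; the raw path is
  retained and equivalence-tested.
* **Bracket-and-bisect schedule.**  Any schedule that finds the
  crossing works; doubling+bisection keeps evaluations logarithmic and
  needs no warm start.
* **Illustrative fit/complexity table values.**  The published
  single-dataset illustrations at `ȳ1 = ȳ2 = 0`, `s² = 1`, `N = 100`
  (e.g. `f0 = 2.816`, `c0 = 0.209`, `f2 = 0.379`) are mutually
  inconsistent with the closed form at those inputs
  (`f0 = 2.8209`, `c0 = 0.19947`, `f2 = 0.5` by symmetry) and evidently
  carry the noise of one simulated dataset or an internal Monte-Carlo
  integrator.  This package implements the closed form; those triples
  are checked only through the `√m` scaling ratios they satisfy.
* **Probabilities printed at two decimals** in the report for
  readability, full precision in the JSON.

## Known limitations

Normal populations only; equal per-group sizes in the design search; no
sequential/updating designs (the package answers the fixed-`N` planning
question); no Jeffreys–Zellner–Siow/Cauchy-prior Bayes factors; no
hypotheses involving more than two means.
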