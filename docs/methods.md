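# Methods

## Model and assumptions

`snapmeta` evaluates a pair of studies — a statistically significant
original and a replication — under a common-true-effect (fixed-effect)
model on the Fisher-z correlation scale. The observed Fisher-z estimate of
a study with total sample size `N` is treated as exactly normal with mean
`θ = atanh(ρ)` and variance `1/(N − 3)`; this is the standard large-sample
approximation and is the only distributional assumption. Two-group designs
enter through `d = t·√(1/n₁ + 1/n₂)` (or pooled-SD Cohen's d from raw
summaries) and the equal-group conversion `r = d/√(d² + 4)`.

The true effect is restricted to an ordered set of snapshot values,
default `ρ ∈ {0, 0.1, 0.3, 0.5}` with exact `θ_x = atanh(ρ_x)`
(0.10034, 0.30952, 0.54931). The posterior model probability of each
snapshot is the normalized product of prior weight and joint likelihood.
These probabilities are *relative* to the snapshot set: they quantify
evidence among the entertained effect sizes, not against an unrestricted
alternative.

The key correction is the original study's likelihood term. Because the
original was selected for significance, its sampling density is normal
*truncated* below at the critical value `θ_cv = z_{1−α/2}·σ̂_o`
(one-sided, in the observed direction; `α = .05` two-tailed by default,
reflecting the reporting convention that only the predicted direction is
published). The truncation denominator `1 − Φ((θ_cv − θ)/σ̂_o)` is the
power of the zero-effect test at true effect `θ`, so the corrected
likelihood inflates the uncorrected one by the reciprocal of power —
a factor of `2/α` (40 at the default) at `θ = 0`, and a factor approaching
1 at snapshots where power is near 1. A study significant in the negative
direction is mirrored (both estimates negated) before analysis, so
snapshots always refer to effect magnitudes. An original exactly at the
critical value counts as significant (inclusive comparison). The method
refuses nonsignificant originals with an explicit error: its conditioning
is undefined for them.

All likelihood work is carried out in log space (`scipy.stats.norm.logpdf`
/ `logsf`) and exponentiated only at the reporting boundary, so distant
snapshots and large samples cannot underflow; posterior normalization uses
`logsumexp`. Prior reweighting operates on equal-prior posteriors directly
(`π*_x ∝ p_x π_x`), and continuous encompassing priors are reduced to
weights by evaluating their density at the snapshot θ values and
normalizing. Degenerate cases — all prior-weighted likelihoods zero —
raise rather than return NaN.

## Operating characteristics (quantile-grid evaluation)

For a condition (true `ρ`, per-study `N`, `α`), the joint distribution of
the published pair is approximated deterministically by a `G × G` grid of
equal-probability points (`G = 5000` by default, i.e. 25 million
combinations):

* Original margin: the sampling distribution of a *published* original is
  the normal truncated at `θ_cv`. With `F` the untruncated CDF, the grid
  takes conditional probabilities `k/(G+1)`, maps them to unconditional
  ones `F(θ_cv) + k·(1 − F(θ_cv))/(G+1)`, and applies the normal quantile.
  Under `ρ = 0` the mass above truncation is exactly `α/2` and the
  probabilities run from `1 − α/2 + (α/2)/(G+1)` upward; under nonzero `ρ`
  the truncated region's mass is the test's power, and using it (rather
  than `α/2`) is what makes the grid cover the whole significant region.
* Replication margin: unconditional quantiles at `k/(G+1)`.

Each grid point carries mass `1/G²` — the construction is equal-probability
averaging, not weighted quadrature. Summaries reported per method and
snapshot: the mean posterior, the fraction with `π > .25` (evidence
increased over the uniform prior) and `π > .75` (positive evidence, the
Bayes-factor-3 convention), the inconclusive fraction (no snapshot above
.75), and the mean of the correlation-scale fixed-effect estimate
(back-transformed *before* averaging; averaging on the Fisher scale first
gives visibly different, wrong, bias values). Exceedance comparisons are
strict; grid points exactly at a threshold would count as not exceeding,
but have measure zero in practice. Evaluation proceeds in chunks of 250
original-grid rows, which keeps the peak working set near 40 MB at
`G = 5000`; a full condition evaluates in a few seconds on one CPU, and
`G = 2000` agrees with `G = 5000` to three decimals on all summaries the
tests check, which is why cheaper grids are used in unit tests.

## Replication sample-size planning

For a chosen snapshot `x`, threshold `a` (default .75) and assurance `b`
(default .8), the planner finds the smallest replication size `n_r ≥ 4`
such that `P(π_x ≥ a) ≥ b` when the true effect equals `θ_x`. The future
replication is integrated over the same `k/(G+1)` quantile grid of its
untruncated sampling distribution; the original study, when incorporated,
enters as a fixed truncated-density likelihood vector — it is observed
data, not a random quantity. The search brackets geometrically
(4, 8, 16, …), bisects, and finally verifies minimality linearly over the
two integers below the candidate, which guards against shallow
non-monotonicity of the discretized exceedance curve. Snapshots already
satisfied at the feasibility floor `n_r = 4` (the smallest size with a
finite Fisher-z standard error) are flagged `at_floor`; a search cap
(default 10⁶) is flagged `unreachable` instead of raising.

A caveat worth stating: near `b` the exceedance probability can be
extremely flat in `n_r` (moving by ~0.002 over several observations), so
the returned integer is sensitive at the ±1–3 level to the integration
grid. The package fixes one convention — the evaluation module's
`k/(G+1)` quantiles at `G = 5000` — rather than tuning per case.

## Synthetic data generator

`simulate.generate_pairs` draws exactly what the evaluation grid
integrates: originals from the truncated normal via inverse-CDF sampling
of the upper tail (uniform on `[F(θ_cv), 1)` through the normal quantile —
cost independent of `α`, no rejection loop), replications unconditionally,
both back-transformed with `tanh` (which bounds `|r| < 1` automatically).
It emulates sampling error and the significance filter only: no
between-study heterogeneity, no questionable research practices, no
selection on the replication, and fixed known sample sizes. Tests passing
on generated data therefore validate the computation under the model's own
assumptions; they do not certify behaviour under heterogeneity or
p-hacking, which the model does not address.

## Batch processing

Tables of pairs (columns `id, r_o, n_o, r_r, n_r[, group]`, comma- or
tab-delimited) are screened row by row: malformed rows and originals not
significant on the Fisher-z z-test are collected into an exclusion report
with reasons, never silently dropped. The significance screen recomputes p
on the Fisher scale, which can disagree with the original publication's
test near the boundary; such rows are excluded and reported. Evidence
categories follow the π > .25 pattern: one exceeding snapshot maps to its
label, two *adjacent* exceeding snapshots to the paired label (e.g.
`0-0.1`), and every other pattern — including three exceedances or
non-adjacent pairs, which the convention leaves undefined — to `other`.
Conclusiveness uses strict π > .75.

## Design choices and limitations

* Significance of correlations is always judged by the Fisher-z z-test,
  matching the model, even where source publications used other tests.
* Correlation-scale confidence intervals transform the Fisher-z Wald
  interval endpoint-wise through `tanh`.
* Custom snapshot sets of any length ≥ 2 are supported everywhere; the
  defaults encode the conventional zero/small/medium/large correlations.
* The evaluation mode uses equal priors only; reweighting is a per-pair
  reporting operation.
* Out of scope by design: continuous posteriors over effect size, Bayes
  factors against composite alternatives, heterogeneity between the two
  studies, more than two studies, and modelling of questionable research
  practices.
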