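# Methods

`polygrade` implements the complete psychometric validation sequence for a
short ordinal scale — dimensionality, competing polytomous IRT models,
global and item-level fit, local dependence, scoring and reliability,
differential item functioning (DIF), person fit, and external validity —
with a synthetic-data generator that reproduces the statistical conditions
of the GAD-7 worker-sample validation (7 items, 4 ordered categories,
n = 2,219, standard-normal latent trait).

## Measurement models

All models are unidimensional, logistic-metric IRT models for responses
coded `0..m-1`.

**Graded response model (GRM).** Boundary probabilities are cumulative
logits, `P(X_i >= k | theta) = 1 / (1 + exp(-a_i (theta - b_ik)))` with
strictly increasing thresholds `b_i1 < ... < b_i,m-1`; category
probabilities are adjacent differences. `GRM_constrained` shares one slope
`a` across items (the tau-equivalence analogue).

**Partial-credit family.** Adjacent-category logits,
`P(X_i = k) ∝ exp(sum_{v<=k} a_i (theta - d_iv))`. GPCM frees per-item
slopes and steps; PCM shares one slope; RSM additionally decomposes the
steps into item location plus a common category pattern
(`d_iv = delta_i + tau_v`, `sum tau_v = 0`).

Free-parameter counts for a 7-item, 4-category scale: GRM and GPCM 28,
GRM_constrained and PCM 22 (one slope + 21 locations/steps), RSM 10 (one
slope + 7 locations + 2 free steps). These counts make `-2LL + 2k`
reproduce the published AIC values exactly.

The standardized loading reported next to each slope is
`F = (a/D) / sqrt(1 + (a/D)^2)` with `D = 1.702`, the usual
logistic-to-normal-ogive scaling.

## Estimation

Marginal maximum likelihood via EM on a fixed quadrature grid:
61 equally spaced nodes on [-6, 6] with renormalized standard-normal
weights (the latent prior). The E-step computes each respondent's
posterior over nodes; the M-step maximizes the expected complete-data
log-likelihood by BFGS — per item for free-slope models, jointly for
shared-parameter models — in unconstrained coordinates (`log a`; ordered
thresholds via log-increments). Convergence is declared when the marginal
log-likelihood improves by less than 1e-5 (maximum 500 cycles); the
log-likelihood is checked to be non-decreasing at every cycle. Standard
errors use the cross-product (BHHH) approximation to the observed
information, with per-respondent scores obtained by central finite
differences on the natural parameter scale.

Degenerate inputs: an item category observed zero times is collapsed into
the adjacent lower category (the remap is recorded on the fitted model);
an item with fewer than two observed categories is an error. Missing
responses are handled by full-information likelihood over each person's
observed items; pairwise-complete observations are used in the polychoric,
Mokken and product-moment stages. How missingness arose in the original
study is unknown, so no imputation is attempted.

## Dimensionality

*Polychoric eigenstructure.* Two-step polychoric correlations (thresholds
from marginal normal quantiles, then ML over the correlation in
(-0.999, 0.999) using bivariate-normal rectangle probabilities). If the
assembled matrix is not positive semi-definite it is repaired by
eigenvalue clipping and rescaling to unit diagonal. The empirical Kaiser
criterion compares sample eigenvalues `lambda_j` to references
`((p - sum_{i<j} lambda_i) / (p - j + 1)) * (1 + sqrt(p/n))^2`, retaining
components while `lambda_j > max(reference_j, 1)`.

*Mokken scalability.* For polytomous items,
`H_ij = cov(X_i, X_j) / covmax(X_i, X_j)` where the maximal covariance
comes from the comonotone (perfect Guttman ordering) coupling of the two
observed marginals; `H_i` and `H` are ratio-of-sums aggregates. The
automated item selection procedure (AISP) is the classical greedy variant:
at each lower bound `c`, seed with the admissible pair maximizing `H_ij`,
grow the scale by the candidate that maximizes scale `H` subject to
positive `H_ij` with all members and scalability >= `c`, then repeat on
the leftovers; unscalable items are labeled 0.

## Global fit and model selection

The limited-information statistic is built from first- and second-order
margins: 21 univariate free category proportions plus 21 bivariate score
product-moments (42 statistics). With residual vector `e`, model-implied
asymptotic covariance `Xi` of the sample margins (computed exactly by
quadrature using conditional independence given theta) and Jacobian `D` of
the implied margins in the free parameters,

    M2 = N e' [Xi^-1 - Xi^-1 D (D' Xi^-1 D)^-1 D' Xi^-1] e,

asymptotically chi-square with `df = 42 - k`. RMSEA is
`sqrt(max(M2 - df, 0) / (df (N-1)))` with a noncentrality-inversion 90%
CI; SRMR is the RMS of inter-item Pearson-correlation residuals; CFI uses
an independence baseline (free marginals, k = 21, df = 21) in
`1 - max(M2 - df, 0) / max(M2_b - df_b, M2 - df, 0)`. AIC/BIC follow the
usual definitions; selection is minimum BIC, ties toward fewer parameters,
confirmed by a Vuong comparison of the top two models.

The Vuong test operates on per-respondent log-likelihood ratios `l_i`:
`omega^2` is their sample variance, tested against zero one-sidedly with a
fourth-moment standard error (distinguishability); superiority is
`z = sum l_i / (sqrt(n) omega)`, interpreted only when distinguishability
is rejected.

A note on the CFI baseline: when the data are truly independent, a
one-factor model reaches the baseline itself (slopes near zero), so both
numerator and denominator vanish and CFI is reported as 1 by convention —
the index is informative only when the fitted model is more constrained
than the data.

## Item fit and local dependence

*Generalized S-chi².* For each item, observed category frequencies within
rest-score groups are compared to model-implied frequencies; the rest
score distribution given theta comes from the recursive convolution of the
other items' category probabilities over the grid, and the joint
integrates over the prior. Collapsing is done at cell level: rows with no
observations are dropped, rows with expected mass below `m` merge into the
nearest row, and cells expected below 1 merge into the adjacent cell with
the larger expectation. `df = sum(cells - 1) - (item parameters)`; items
ending with fewer than 2 groups or df < 1 are flagged untestable. Item
RMSEA reuses the RMSEA formula with the item statistic and df.

*Jackknife Slope Index (JSI).* For each ordered pair (i, j), the model is
refit without item i and `JSI_ij = (a_j - a_j^(-i)) / se(a_j^(-i))`; local
dependence inflates slopes, so removing the partner shifts them by many
standard errors. The index is computed in both directions per unordered
pair and the direction of larger magnitude is reported (the published
triangular table does not state a direction). The flagging threshold is
`mean + 2.58 * SD` over the signed reported entries (two-sided p < .01);
pairs with `|value| > |threshold|` are flagged. Refits that fail leave the
pair missing and excluded from the moments.

## Scoring, reliability, person fit

EAP scores are posterior means over the grid under the standard-normal
prior, with posterior SDs; an all-missing respondent recovers the prior
(EAP 0, PSD 1) and is flagged. Item information is the score-function
variance `sum_k P_k'^2 / P_k` (analytic derivatives for the GRM, central
differences for the adjacent-category family); test information is the
pointwise sum. Conditional reliability is `I(theta) / (I(theta) + 1)`;
the single-number empirical reliability is
`var(EAP) / (var(EAP) + mean(PSD^2))` — the paper labels its 0.85 both
"marginal" and "empirical" without printing a formula, so this standard
empirical definition is used and the published value is matched to ±0.03.

Person fit is the standardized log-likelihood Zh evaluated at the EAP
estimate (the estimate the scoring stage produces); the conservatism of
plugging in an estimated theta is documented, not corrected. Flags use
|Zh| > 2. Zh is additionally correlated with external variables
(Fisher-z CIs) to check that aberrance is unrelated to the criteria.

## Differential item functioning

Hybrid ordinal-logistic DIF: per item, proportional-odds models
`response ~ theta`, `+ group`, `+ theta x group` (the matching theta is
the EAP score from the pooled fit; a single pass, no purification).
Uniform DIF is the likelihood-ratio chi-square of the group main effect,
non-uniform DIF of the interaction, df = 1 each at alpha = 0.01. Effect
sizes are Cox-Snell `1 - exp(-(2/n)(LL_m - LL_0))` and Nagelkerke
(Cox-Snell divided by its maximum), with adjacent-model deltas judged at
0.02 / 0.13 / 0.26 (low / moderate / large; below 0.02 trivial). The
proportional-odds fits use statsmodels' ordered model; the intercept-only
null log-likelihood is the closed-form multinomial value. Because a
shifted item also distorts the pooled matching score, injected DIF
inflates neighboring items' rejection rates somewhat — the injected item
still dominates, which is what the power harness asserts.

## Synthetic data generator

The generator inverts the graded response model: one uniform draw per
response with the coupling `X = #{k : u < P(X >= k)}` (exact because
boundary probabilities decrease in k), theta standard normal by default
(a fixed-theta mode exists for deterministic limits). Defaults are the
published GAD-7 worker-sample estimates (slopes 2.48-4.40, thresholds
-0.13 to 1.87), kept in a single named fixture (`GAD7_ITEM_PARAMS`) so
every test cites one source of truth. Options: per-item focal-group
threshold shifts and slope ratios (DIF), a fraction of uniform-random
aberrant responders (the person-fit stage's target; the original study
names no mechanism), and external variables generated as
`r * theta + sqrt(1 - r^2) * noise` then affinely rescaled — the study
reports target correlations only, not scales. An adjacent-category
generator covers RSM/PCM/GPCM, enforcing each model's equality
constraints.

What the generator does **not** emulate: multidimensionality or method
factors, response styles, skewed latent traits (anxiety in workers is
plausibly right-skewed; a standard-normal trait is the MML-consistent
default), item-level missingness patterns, and sampling clustering across
the three pooled sub-studies. Tests passing on these simulations show the
pipeline recovers the published structure when the model holds; they do
not certify behavior under those real-data complications.

## Problem sizes used in the test suite

The suite favors exact small-instance oracles (enumeration, brute-force
optimization, dense quadrature) plus a few simulation checks at realistic
sizes: marginal-convergence checks at n = 50,000; parameter recovery and
reliability at the study size n = 2,219 over 20 seeds; AISP stability over
100 seeds; DIF power over 3-5 seeds at n = 2,000; local-dependence
injection at n = 1,200-1,500 with 5 items. The end-to-end pipeline test
runs all five models at n = 700.

## Known limitations

- No Bayesian estimation, multidimensional/bifactor models, or nominal
  response model; no Q3-type local-dependence statistics alongside JSI.
- No Snijders-type correction to Zh for estimated theta.
- Vuong distinguishability uses a normal approximation to the variance
  statistic rather than the weighted-chi-square null.
- DIF is two-group, single-pass (no purification, no Mantel-Haenszel or
  IRT-LR variants).
- The empirical-reliability definition and the JSI direction convention
  are documented choices; the source study does not state its own.
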