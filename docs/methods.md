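# Methods

This note documents the statistical procedures implemented in
`emospace`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic-data validation does
and does not establish.

## The data model

The package analyses slider ratings of emotion experience on a 1–7
scale. Three study designs are supported: emotions evoked by written
narratives or by video clips (each stimulus rated on one assigned
scale per session, ~20 raters per scale, 8 retest trials per session),
and real-life experience sampling (each instance rated once by the
person who lived it, across survey waves). The raw unit is the
long-format `RatingTable`; multivariate analyses operate on the
`RatingMatrix` — rater-mean aggregates for evoked domains, raw rows
for real-life instances, where averaging across people would destroy
the idiosyncratic signal.

Exclusions run at three levels with configurable thresholds
(defaults: trials with timeouts or reaction time < 400 ms; sessions
with more than 1 of 3 failed attention checks, retest reliability more
than 3 SD below their same-scale/same-stimulus-set cohort mean
(strict <), or more than 10% invalid trials; participants with more
than 3 invalid sessions). The reliability screen needs at least 3
retest pairs — a Pearson correlation is undefined below that — so
sessions with fewer pairs are screened by the invalid-trial rule
alone.

## Synthetic ground truth

Every stage is validated by recovery against a generator with known
parameters. The generative model is an oblique common-factor model:

- factor scores `F ~ MVN(0, Φ)` per stimulus, with `Φ` unit-diagonal
  (default: k = 3 factors, pairwise correlation 0.2 — a
  valence/arousal/generalizability-like structure);
- a bipolar simple-structure loading matrix `Λ` (23 scales by default,
  primary loadings 0.6–0.85 with alternating signs, small
  cross-loadings), uniquenesses `Ψ` completing each scale to unit
  latent variance;
- slider mapping `clip(4 + g·(FΛ' + e), 1, 7)` with default gain
  g = 1, which leaves ≥ 99% of draws inside the bounds — clipping
  rather than truncated sampling, because bounded sliders censor
  rather than resample;
- raters add a stable bias (SD 0.3) and trial noise (SD 0.8), both in
  slider units; 8 retest stimuli per session are drawn uniformly
  without replacement and rated with fresh noise. Reaction times are
  log-normal (median ~2 s); invalid trials and failed attention checks
  can be planted at chosen rates for exclusion tests.

Presets mirror the three study scales (150×23, 998×23, 12861×18).
What the generator does *not* emulate: ordinal response styles,
scale-specific variances, rater drift over a session, non-Gaussian
factor distributions, and any semantic relation between scales.
Passing recovery tests therefore shows the estimators are correct and
well-calibrated under the stated model, not that real rating data
satisfy that model.

Individual differences are planted directly at the level of
participant mean ratings: a trait effect `r` makes the participant's
standardized scale mean correlate `r` with the standardized trait;
binary group effects are Cohen's-d mean shifts. Residual variance is
scaled so the marginal is unit variance, so planted `r` values are
population correlations.

## Reliability

Test–retest reliability is the per-session Pearson correlation of the
(main, retest) pairs; sessions with fewer than 3 pairs or zero
variance are undefined and excluded from medians (not coded as 0).
Split-half reliability randomly halves the raters of each
(scale, domain) cohort, correlates the two per-stimulus mean vectors,
and repeats 50 times. With signal variance σ²ₛ and rater noise σ²ₑ in
halves of m raters the population value is 1/(1 + σ²ₑ/(m·σ²ₛ)); the
generator reproduces this closed form, and the Spearman–Brown increase
with rater count is verified by simulation.

Readability uses the Flesch–Kincaid grade,
`0.39·(words/sentences) + 11.8·(syllables/words) − 15.59`, with a
dictionary-free syllable counter (maximal vowel runs, y vocalic,
silent-e correction, floor 1). The counter is a documented heuristic;
readability is reported, never used as a gate. Scale exclusion is by
an explicit named roster (the conventional five low-quality scales,
28 → 23) or an optional numeric threshold for new data.

## Representational similarity

First-order structure is the scale-by-scale Pearson matrix over
stimuli. Second-order similarity Fisher-z-transforms the lower
triangles (|r| = 1 clamped at atanh(1 − 1e−12)) and takes the Spearman
rank correlation — the z-transform is monotone, so it cannot change ρ,
but it is applied as part of the documented procedure. The null
distribution permutes rows and columns of one matrix with a *single
shared* permutation (preserving symmetry); p uses the add-one rule
(1 + #{ρ_perm ≥ ρ_obs})/(n + 1), so it is never exactly zero. Display
ordering is dendrogram leaf order (average linkage on 1 − r with
optimal leaf ordering).

## Factor retention

Six classical criteria are implemented on principal-component
eigenvalues of the full correlation matrix (the convention of the
non-graphical scree literature): parallel analysis against the
rank-wise mean of random-normal eigenvalues (a `centile` option gives
the stricter quantile variant, which is better calibrated on pure
noise — the mean rule's leading run can ride a globally elevated
noise spectrum), the optimal coordinate (linear extrapolation through
the next and last eigenvalue), the acceleration factor (rank before
the largest second difference, floored at 1), Very Simple Structure at
complexity 1, Velicer's MAP (minimum mean squared partial correlation
after partialling k components; degenerate no-structure input returns
1 by convention), and an empirical BIC (χ² − df·ln n over ML factor
solutions).

The empirical cross-validation splits stimuli in half (20 iterations):
EFA (minres + oblimin) on half A gives the explained variance (mean
communality) and a loading pattern — each scale is assigned to *every*
factor whose absolute pattern loading exceeds 0.2, leaving genuine
cross-loadings free rather than forcing single membership. A CFA with
that pattern (maximum likelihood under multivariate normality; free
factor correlations via a unit-row-norm Cholesky parametrization;
analytic gradients) is fitted to half B, and
`RMSEA = sqrt(max(χ²−df, 0)/(df·(N−1)))` recorded. Iterations where a
factor receives no items, df ≤ 0, or the optimizer fails are excluded
from the means and logged, never imputed. The elbow rule selects the
largest k whose mean RMSEA improves on k−1 by more than 0.01 (the
original choice was made by inspection; the tolerance is exposed).

## Factor models

Minres extraction concentrates the objective: for given uniquenesses
ψ the best rank-k common part is the eigen-truncation of R − diag(ψ),
and the residual sum of squares equals the sum of squared discarded
eigenvalues, whose gradient in ψ is available in closed form
(−2·Σ_{j>k} λ_j v²_ji). This full-matrix form lets ψ absorb the
diagonal slack and agrees with the off-diagonal criterion at the
optimum. Heywood cases are capped at unit communality with a warning
and flagged. Rotations delegate to the gradient-projection routines in
statsmodels: oblimin with γ = 0 (direct quartimin) for EFA, varimax
for PCA. Factors are sign-oriented so each column's largest loading is
positive. Oblique factor scores use the Ten Berge
correlation-preserving estimator, so the sample correlation of the
scores equals Φ exactly. "Share of common variance" is the per-factor
sum of squared *structure* loadings normalized across retained factors
(the oblique convention).

Tucker congruence between loading matrices aligns the comparison
matrix by orthogonal Procrustes first (absorbing sign flips, column
permutations, and rotational indeterminacy), then reports the
per-column normalized cross-product. Robustness is assessed two ways:
random stimulus decimation (re-fit on shrinking subsets, congruence
against the full solution, 20 randomizations per size; preset step
sizes 5/25/250 for the three domains) and redundancy-ordered scale
removal (repeatedly drop the scale with the highest mean correlation
with the rest, ties broken by scale id; refit and correlate factor
scores, matched by greedy maximal-|r| one-to-one assignment with sign
alignment). A null baseline scrambles each column independently to
show where congruence falls when structure is destroyed.

The linear autoencoder is fitted exactly: with squared loss and linear
activations the optimal one-hidden-layer autoencoder spans the top-k
principal subspace of the training data, so the SVD gives the global
optimum of the least-squares training problem directly, and training
error coincides with PCA reconstruction error by construction (the
test verifies this against an independent PCA). Cross-validation
trains on the aggregate of a random half of the raters and scores
reconstruction of the other half's aggregate.

## Principal preserved components

PPCA eigen-decomposes the symmetrized cross-covariance
(X'Y + Y'X)/2 of two column-centered datasets; with Y = X this is
exactly PCA (asserted to 1e−8). Centering is applied within each
half-set — the procedure needs covariance semantics and the halves'
means differ by sampling noise. Significance uses the repeated-split
leave-one-out procedure: the ratings of each (stimulus, scale) cell
randomly halved, independently per stimulus — one rater's trials
scatter across both half-sets, which keeps the two halves free of any
systematic rater-level alignment — each stimulus held
out in turn, components fitted on the remainder with a deterministic
sign convention (largest-|weight| element positive — alignment must
not reference the held-out row, which would leak), held-out rows
projected in both sets, per-component correlations computed after
partialling out all previous components' scores by OLS, 20
repetitions, one-tailed Wilcoxon signed-rank per component at
Bonferroni α/m. The reported "significant count" is the contiguous
leading run (a total count is also exposed).

The splitting granularity matters more than it looks. Halving whole
raters (sessions) instead of each stimulus's ratings leaves every
repetition re-splitting the same rater pool, so each dataset's noise
alignments give trailing components small but *repetition-stable*
held-out correlations; the 20-repetition Wilcoxon then certifies
spurious dimensions under the null (~15–25% of null datasets at desk
scales) and an extra component beyond a rank-3 truth. The per-stimulus
split scatters each rater's trials over both halves, which restores
type-I calibration and exact recovery of the planted rank; it is the
implemented (and originally described) procedure. Separately, the test
is extraordinarily sensitive: any reliable shared variance — including
slider-clipping curvature at high gain — is certified, so read the
significant count as "dimensions with detectable reliable shared
variance", not as the dimensionality of the dominant structure.

## Embedding

UMAP reduces the rating space to 2-D. The neighborhood size is chosen
by split-half cross-validation: fit on a random half, map the held-out
half with the fitted model's transform (the original selection was by
inspection of the two metrics; the transform-based mapping is this
package's documented choice), and score trustworthiness (default
k = 5, exposed) and the Spearman correlation of pairwise Euclidean
distances. The chosen size maximizes the rank-sum of the two mean
metrics — a documented combination rule standing in for the original
visual judgment.

## Clustering and unimodality

Hierarchical clustering uses Euclidean distance with Ward linkage on
the raw 1–7 ratings, deliberately unstandardized: scale variances
carry information about how discriminative each scale is. K-means
recovery of intended categories (10 restarts, best inertia, seed
recorded) is scored by ARI and AMI with the contingency table
attached. Unimodality of the pairwise-distance distribution is tested
with Hartigan's dip statistic, computed by the classical
convex-minorant/concave-majorant algorithm (the implementation is
verified, to 1e−8, against an independent linear-programming
formulation that optimizes over piecewise-linear unimodal CDFs with an
enumerated modal segment). P-values are Monte-Carlo calibrated against
the uniform null of the same sample size (the least favorable unimodal
case; 2000 replicates by default, add-one corrected) rather than read
from precomputed tables.

Prototypical basic-emotion instances require a rating strictly above 6
on the category's scale, then rank by Euclidean distance to the
perfect prototype (7 on the category scale, 1 elsewhere), ties broken
by instance id, up to 5 per category.

## Stimulus sampling

Subset size is judged by the PCA-plateau curve: the mean (over 100
random subsets) number of PCs needed for 80% of total variance,
plateau declared when the mean comes within 0.5 PCs of the full-set
value (the original judgment was visual; the tolerance is exposed).
Maximum-variation selection greedily grows a subset from every
possible starting stimulus, each addition maximizing the summed
distance to the already-selected set, and keeps the run with the
largest total pairwise distance (ties lexicographic by id; a max-min
criterion is exposed but off by default). Features are not
standardized before distances by default (exposed as a flag upstream
of the call). On small instances the greedy-over-all-starts objective
is verified against exhaustive subset enumeration (≥ 95% of the
optimum).

## Individual differences

Evoked ratings are centered per (stimulus, scale) across participants
before session means are taken, isolating each participant's rating
bias from stimulus content; centering is idempotent and singleton
cells center to 0 (logged). Real-life means are taken across waves for
participants with complete data from all 15 waves only, optionally
corrected by the participant's evoked baseline bias. The association
screen crosses every scale with every variable — Pearson for
continuous traits, Welch's t for binary groups, oriented group 1 minus
group 0 — with Bonferroni correction over the entire grid (the
displayed family; per-variable families are configurable).

## Validation design and problem sizes

The recovery suite runs at the narrative study scale (150 stimuli ×
23 scales × 20 raters, 3 oblique factors) with 20 replicate studies
for factor recovery and retention, 5 for PPCA recovery, 20 for the
PPCA null, 200 replicate experiments for permutation-p uniformity and
the null association screen, 10 for dip calibration, and 50 random
instances for the sampling oracle; the acceptance script uses 10
replicates for the retention stage. These sizes give the simulated
rates binomial standard errors of a few percent, so rate assertions
carry explicit finite-sample margins: a simulated family-wise error at
nominal 5% over 200 replicates has SD ≈ 1.5%, and a hard cut at the
nominal value would reject a correct implementation almost half the
time; tests therefore bound the observed rate by a one-sided 99%
binomial (or Poisson, for counts) limit around the nominal level.

## Known limitations

- The CFA assumes multivariate normality and an unweighted ML
  discrepancy; no robust corrections or ordinal estimators.
- The dip p-value is Monte-Carlo, so its resolution is 1/(B + 1).
- The minres/oblimin solutions match the conventional implementations
  up to optimizer tolerance, not bit-for-bit.
- UMAP determinism holds for a fixed seed and version but coordinates
  are not meaningful beyond neighborhood relations.
- The generator's slider clipping slightly attenuates covariances at
  gain 1; closed-form moment checks use smaller gains where clipping
  is provably absent.
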