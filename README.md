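# emospace

Dimensional analysis of emotion-experience rating data.

## The problem

How many dimensions does subjective emotion experience have? Studies
that collect slider ratings (1–7) of emotion episodes — evoked by
narratives or video clips, or sampled from daily life — on a couple of
dozen affective scales need a reproducible pipeline to answer that:
screening scales for reliability, comparing correlation structure
across stimulus domains, deciding how many factors to retain, fitting
and stress-testing the factor model, asking whether the space is a
continuum or a set of discrete clusters, and screening for individual
differences in rating style. `emospace` implements that pipeline for
psychometricians and affective scientists, together with a
synthetic-data generator with known latent structure so that every
stage can be validated by parameter recovery.

## The model

The core is the oblique common-factor model of the stimulus-by-scale
rating matrix. With loadings Λ (scales × k), factor correlations Φ,
and uniquenesses Ψ, the correlation structure is

    R ≈ Λ Φ Λ' + Ψ

estimated by minimum residual (minres) extraction with oblimin
rotation and Ten Berge factor scores. Around it:

- **Reliability** — within-subject test–retest r over the 8 retest
  trials per session; between-subject split-half r over 50 random
  rater splits; Flesch–Kincaid readability of scale definitions.
- **RSA** — scale × scale Pearson matrices per domain; second-order
  Spearman ρ of Fisher-z lower triangles; 10,000-draw joint
  row/column permutation test.
- **Retention** — parallel analysis, optimal coordinate, acceleration
  factor, VSS, Velicer MAP, empirical BIC, plus an EFA→CFA split-half
  cross-validation over k = 1..8 scored by explained variance and
  RMSEA.
- **Robustness** — Tucker congruence (orthogonal Procrustes aligned)
  under random stimulus decimation and redundancy-ordered scale
  removal; PCA (varimax) and an exactly-solved linear autoencoder as
  converging estimators.
- **PPCA** — principal preserved components: eigenvectors of the
  symmetrized cross-covariance of two rater half-sets (reduces to PCA
  when the sets coincide), with a repeated-split leave-one-out
  Wilcoxon test per component.
- **Embedding / clustering** — UMAP with cross-validated neighborhood
  size; Ward/Euclidean hierarchical clustering on raw ratings; K-means
  recovery of intended categories (ARI/AMI); Hartigan's dip test of
  the pairwise-distance distribution.
- **Stimulus sampling** — PCA-plateau subset sizing and greedy
  maximum-variation selection over all starts.
- **Individual differences** — stimulus-centered participant means and
  a Pearson/Welch association grid with Bonferroni correction.

## Worked example

Simulate a narrative-scale study (150 stimuli × 23 scales, 20 raters
per scale, 3 planted oblique factors), aggregate it, choose k, and fit
the factor model:

```python
from emospace import (
    default_truth, generate_rater_ratings, apply_exclusions,
    aggregate_matrix, cv_retention, ExploratoryFactorAnalysis,
    tucker_congruence,
)

truth = default_truth("narrative", seed=1)
table = generate_rater_ratings(truth)
table, report = apply_exclusions(table)
matrix = aggregate_matrix(table, "narrative")

retention = cv_retention(matrix, n_iter=20, seed=1)
print("chosen k:", retention.chosen_k)
print(retention.mean_curves.round(3))

res = ExploratoryFactorAnalysis(matrix).fit(retention.chosen_k)
print(res.var_proportions.round(3))
print("recovery:",
      tucker_congruence(truth.loadings, res.loadings.to_numpy()).phi.round(3))
```

Output:

```
chosen k: 3
   explained_variance  rmsea
1               0.202  0.173
2               0.368  0.136
3               0.509  0.061
4               0.540  0.059
5               0.569  0.057
6               0.598  0.054
7               0.626  0.050
8               0.653  0.047
F1    0.358
F2    0.322
F3    0.320
Name: prop, dtype: float64
recovery: [0.993 0.991 0.984]
```

The held-out RMSEA curve drops sharply until k = 3 and flattens, so
the cross-validation elbow retains three factors; they carry 36/32/32%
of the common variance, and each recovered factor matches its planted
counterpart with Tucker congruence ≥ 0.98 — the generator's
valence/arousal/generalizability-like structure is recovered
essentially exactly.

A thin CLI wraps the common steps
(`emospace simulate|exclude|aggregate|reliability|rsa|retain|efa|ppca|cluster|sample`);
the Python API is the primary interface.

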