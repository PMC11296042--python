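"""EFA/PCA estimation, Tucker congruence, scores, and robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emospace.factor import (
    ExploratoryFactorAnalysis,
    PrincipalComponents,
    tucker_congruence,
)
from emospace.robustness import (
    decimate_scales,
    decimate_stimuli,
    null_congruence,
    redundancy_order,
)
from emospace.rsa import CorrelationStructure, scale_corr
from emospace.simulate import default_truth, generate_latent_dataset


@pytest.fixture(scope="module")
def clean_matrix():
    """Essentially noise-free 3-factor data (tiny uniquenesses)."""
    truth = default_truth("narrative", seed=41)
    truth.uniqueness = np.full(23, 0.01)
    truth.gain = 0.5
    truth.n_stimuli = 400
    mat, _ = generate_latent_dataset(truth)
    return mat, truth


class TestEFA:
    def test_noise_free_recovery(self, clean_matrix):
        mat, truth = clean_matrix
        res = ExploratoryFactorAnalysis(mat).fit(3)
        cong = tucker_congruence(truth.loadings, res.loadings.to_numpy())
        assert cong.min >= 0.99

    def test_rank_one_structure(self, rng):
        """Unit-variance variables built as lam*f + sqrt(1-lam^2)*noise
        have correlation matrix lam lam' + diag(1 - lam^2); the
        one-factor solution recovers lam itself."""
        lam = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        n = 40_000
        f = rng.standard_normal(n)
        x = np.outer(f, lam) + rng.standard_normal((n, 5)) * np.sqrt(1 - lam**2)
        res = ExploratoryFactorAnalysis(pd.DataFrame(x)).fit(1)
        got = res.loadings.to_numpy().ravel()
        assert np.abs(got - lam).max() < 0.02
        assert np.abs(res.residual_corr).max() < 0.02

    def test_variance_proportions_sum_to_one(self, narrative_matrix):
        res = ExploratoryFactorAnalysis(narrative_matrix).fit(3)
        assert res.var_proportions.sum() == pytest.approx(1.0)

    def test_tenberge_scores_reproduce_phi(self, narrative_matrix):
        res = ExploratoryFactorAnalysis(narrative_matrix).fit(3)
        score_corr = np.corrcoef(res.scores.to_numpy().T)
        assert np.abs(score_corr - res.phi).max() < 1e-8

    def test_residuals_shrink_with_k(self, narrative_matrix):
        model = ExploratoryFactorAnalysis(narrative_matrix)
        ss = [
            (model.fit(k).residual_corr ** 2).sum() for k in (1, 2, 3, 4)
        ]
        assert ss[0] > ss[1] > ss[2] >= ss[3] - 1e-9

    def test_k_bounds_checked(self, narrative_matrix):
        model = ExploratoryFactorAnalysis(narrative_matrix)
        with pytest.raises(ValueError):
            model.fit(0)
        with pytest.raises(ValueError):
            model.fit(23)

    def test_summary_mentions_fit(self, narrative_matrix):
        s = ExploratoryFactorAnalysis(narrative_matrix).fit(2).summary()
        assert "Pattern loadings" in s and "k=2" in s


class TestPCA:
    def test_full_rank_reproduces_total_variance(self, narrative_matrix):
        res = PrincipalComponents(narrative_matrix).fit(23, rotation=None)
        lam = res.loadings.to_numpy()
        assert np.trace(lam @ lam.T) == pytest.approx(23.0, rel=1e-6)

    def test_congruent_with_efa_on_strong_factors(self, clean_matrix):
        mat, _ = clean_matrix
        efa = ExploratoryFactorAnalysis(mat).fit(3)
        pca = PrincipalComponents(mat).fit(3)
        assert efa.congruence(pca).min >= 0.95

    def test_varimax_loadings_orthogonal_phi(self, narrative_matrix):
        res = PrincipalComponents(narrative_matrix).fit(3)
        assert np.allclose(res.phi, np.eye(3))


class TestTuckerCongruence:
    def test_identity(self, rng):
        a = rng.standard_normal((10, 3))
        assert tucker_congruence(a, a).phi == pytest.approx([1, 1, 1])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_sign_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((8, 3))
        perm = rng.permutation(3)
        signs = rng.choice([-1.0, 1.0], size=3)
        b = a[:, perm] * signs
        assert tucker_congruence(a, b).min >= 1.0 - 1e-8

    def test_unit_vector_dot_product_without_alignment(self):
        a = np.array([[1.0], [0.0]])
        b = np.array([[0.6], [0.8]])
        res = tucker_congruence(a, b, procrustes=False)
        assert res.phi[0] == pytest.approx(0.6)

    def test_zero_column_undefined(self):
        a = np.ones((4, 2))
        b = np.column_stack([np.ones(4), np.zeros(4)])
        with pytest.warns(UserWarning, match="zero-norm"):
            res = tucker_congruence(a, b, procrustes=False)
        assert np.isnan(res.phi[1])


class TestRobustness:
    def test_full_set_congruence_is_one(self, narrative_matrix):
        curves = decimate_stimuli(narrative_matrix, k=3, step=50, n_rand=3, seed=0)
        top = curves.curves.query("size == 150")
        assert np.allclose(top["similarity"], 1.0)

    def test_strong_factors_robust_to_decimation(self, narrative_matrix):
        curves = decimate_stimuli(
            narrative_matrix, k=3, step=40, n_rand=5, seed=0, min_size=30
        )
        means = curves.mean_by_size()
        assert means.loc[30:].min().min() >= 0.9

    def test_noise_congruence_below_structure(self, rng):
        x = pd.DataFrame(rng.standard_normal((100, 10)))
        null = null_congruence(x, k=2, n_rep=5, seed=0)
        assert np.nanmean(np.abs(null)) < 0.9

    def test_redundancy_order_duplicates_first(self, rng):
        z = rng.standard_normal(80)
        df = pd.DataFrame(
            {"dup_a": z + rng.standard_normal(80) * 0.05,
             "dup_b": z + rng.standard_normal(80) * 0.05,
             "indep": rng.standard_normal(80)}
        )
        order = redundancy_order(scale_corr(df))
        assert order[0] in ("dup_a", "dup_b")
        assert "indep" not in order[:1]

    def test_redundancy_tie_break_on_identity(self):
        names = ["c", "a", "b", "d"]
        c = CorrelationStructure(
            pd.DataFrame(np.eye(4), index=names, columns=names)
        )
        assert redundancy_order(c) == ["a", "b"]

    def test_scale_decimation_keeps_factor_scores(self, narrative_matrix):
        curves = decimate_scales(narrative_matrix, k=3)
        sub = curves.curves.query("size >= 18")
        assert sub["similarity"].min() >= 0.9
        # matching is one-to-one: k entries per step
        per_step = curves.curves.groupby("step")["factor"].nunique()
        assert (per_step == 3).all()
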