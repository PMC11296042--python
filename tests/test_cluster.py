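"""Hierarchical/K-means clustering, dip unimodality, basic-emotion selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from sklearn.metrics import adjusted_rand_score

from emospace._dip import dip_statistic, dip_test
from emospace.cluster import (
    dip_unimodality,
    hac,
    kmeans_agreement,
    select_basic_instances,
)
from emospace.simulate import ClusterSpec, default_truth, generate_categorical_dataset


@pytest.fixture(scope="module")
def two_cluster_matrix():
    truth = default_truth("narrative", seed=3)
    truth.n_stimuli = 120
    truth.clusters = ClusterSpec(
        n_categories=2, centroids=np.array([[4.0, 0, 0], [-4.0, 0, 0]])
    )
    mat, _ = generate_categorical_dataset(truth)
    return mat


def _dip_lp(x):
    """Independent brute-force dip: LP over piecewise-linear unimodal
    CDFs (slopes nondecreasing up to a modal segment, nonincreasing
    after), mode segment enumerated."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    dx = np.diff(x)
    dx = np.where(dx == 0, 1e-12, dx)
    best = np.inf
    for jmode in range(n - 1):
        a_ub, b_ub = [], []
        for i in range(n):
            for target in (i / n, (i + 1) / n):
                r = np.zeros(n + 1); r[i] = 1; r[n] = -1
                a_ub.append(r); b_ub.append(target)
                r = np.zeros(n + 1); r[i] = -1; r[n] = -1
                a_ub.append(r); b_ub.append(-target)
        for i in range(n - 1):
            r = np.zeros(n + 1); r[i] = 1; r[i + 1] = -1
            a_ub.append(r); b_ub.append(0.0)
        for i in range(n - 2):
            si = np.zeros(n + 1); si[i] = -1 / dx[i]; si[i + 1] = 1 / dx[i]
            s2 = np.zeros(n + 1); s2[i + 1] = -1 / dx[i + 1]; s2[i + 2] = 1 / dx[i + 1]
            if i < jmode:
                a_ub.append(si - s2); b_ub.append(0.0)
            else:
                a_ub.append(s2 - si); b_ub.append(0.0)
        c = np.zeros(n + 1); c[n] = 1.0
        res = linprog(c, A_ub=np.array(a_ub), b_ub=np.array(b_ub),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


class TestDip:
    def test_matches_lp_oracle_on_small_samples(self, rng):
        for trial in range(8):
            n = int(rng.integers(5, 13))
            if trial % 2:
                x = rng.standard_normal(n)
            else:
                x = np.concatenate(
                    [rng.standard_normal(n // 2), rng.standard_normal(n - n // 2) + 6]
                )
            assert dip_statistic(x) == pytest.approx(_dip_lp(x), abs=1e-8)

    def test_evenly_spaced_sample_attains_minimum(self):
        for n in (6, 20, 100):
            assert dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n))

    def test_bimodal_rejected_unimodal_not(self, rng):
        uni = rng.standard_normal(400)
        bim = np.concatenate([rng.standard_normal(200), rng.standard_normal(200) + 5])
        _, p_uni = dip_test(uni, n_boot=300, seed=0)
        _, p_bim = dip_test(bim, n_boot=300, seed=0)
        assert p_uni > 0.05
        assert p_bim < 0.01

    def test_p_roughly_uniform_under_uniform_null(self, rng):
        from scipy import stats

        ps = [
            dip_test(rng.random(150), n_boot=200, seed=i)[1] for i in range(60)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestHAC:
    def test_two_cut_recovers_planted_clusters(self, two_cluster_matrix):
        res = hac(two_cluster_matrix)
        ari = adjusted_rand_score(two_cluster_matrix.row_labels, res.cuts[2])
        assert ari == 1.0

    def test_duplicated_rows_merge_at_height_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]])
        res = hac(df)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_row_order_invariance(self, two_cluster_matrix, rng):
        perm = rng.permutation(len(two_cluster_matrix.values))
        shuffled = two_cluster_matrix.values.iloc[perm]
        a = hac(two_cluster_matrix).cuts[2]
        b = hac(shuffled).cuts[2]
        inv = np.empty_like(perm); inv[perm] = np.arange(len(perm))
        assert adjusted_rand_score(a, b[inv]) == 1.0


class TestKMeans:
    def test_self_reference_perfect(self, two_cluster_matrix):
        res = kmeans_agreement(two_cluster_matrix, two_cluster_matrix.row_labels,
                               seed=0)
        again = kmeans_agreement(two_cluster_matrix, res.labels, seed=0)
        assert again.ari == 1.0 and again.ami == pytest.approx(1.0, abs=1e-9)

    def test_random_labels_score_near_zero(self, two_cluster_matrix, rng):
        aris = []
        for _ in range(100):
            fake = rng.integers(0, 2, size=len(two_cluster_matrix.values))
            res = kmeans_agreement(two_cluster_matrix, fake, seed=0, n_init=2)
            aris.append(res.ari)
        assert abs(np.mean(aris)) < 0.02

    def test_label_renaming_invariance(self, two_cluster_matrix):
        ref = np.asarray(two_cluster_matrix.row_labels)
        a = kmeans_agreement(two_cluster_matrix, ref, seed=0).ari
        b = kmeans_agreement(two_cluster_matrix, 5 - ref, seed=0).ari
        assert a == pytest.approx(b)

    def test_six_well_separated_categories(self):
        truth = default_truth("narrative", seed=9)
        truth.n_stimuli = 300
        centroids = np.vstack([np.eye(3), -np.eye(3)]) * 6
        truth.clusters = ClusterSpec(
            n_categories=6, centroids=centroids, within_sd=1.0
        )
        mat, _ = generate_categorical_dataset(truth)
        res = kmeans_agreement(mat, mat.row_labels, seed=0)
        assert res.ari >= 0.9
        assert res.contingency.to_numpy().sum() == 300


class TestDipOnMatrix:
    def test_identical_rows_degenerate(self):
        df = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError, match="identical"):
            dip_unimodality(df)


class TestBasicInstances:
    @pytest.fixture()
    def matrix6(self):
        scales = ["happiness", "surprise", "fear", "anger", "disgust", "sadness"]
        rows = {
            "perfect_happy": [7, 1, 1, 1, 1, 1],
            "boundary_happy": [6.0, 1, 1, 1, 1, 1],
            "good_happy": [6.5, 1.5, 1, 1, 1, 1],
            "ok_happy": [6.2, 2, 2, 1, 1, 1],
            "fearful": [1, 1, 6.8, 1, 1, 1],
            "neutral": [4, 4, 4, 4, 4, 4],
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=scales)

    def test_perfect_instance_selected_first(self, matrix6):
        sel = select_basic_instances(matrix6)
        assert sel["happiness"][0] == "perfect_happy"

    def test_boundary_six_excluded(self, matrix6):
        sel = select_basic_instances(matrix6)
        assert "boundary_happy" not in sel["happiness"]

    def test_ranked_by_distance_and_capped(self, matrix6):
        sel = select_basic_instances(matrix6, per_category=2)
        assert sel["happiness"] == ["perfect_happy", "good_happy"]

    def test_empty_category_logged_not_fatal(self, matrix6):
        sel = select_basic_instances(matrix6)
        assert sel["anger"] == []
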