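"""Test-retest, split-half, scale flagging, and readability."""

import numpy as np
import pytest

from emospace.data import RatingTable
from emospace.reliability import (
    DEFAULT_LOW_QUALITY_SCALES,
    count_syllables,
    fk_grade,
    flag_low_quality,
    scale_quality,
    split_half,
)
from emospace.reliability import test_retest as retest_corr
from emospace.simulate import default_truth, generate_rater_ratings
from conftest import make_table


def _session_with_pairs(pairs, scale="happy"):
    rows = []
    for i, (main, retest) in enumerate(pairs):
        rows.append(("p1", "s1", "narrative", f"st{i}", scale, main, "main"))
        rows.append(("p1", "s1", "narrative", f"st{i}", scale, retest, "retest"))
    return RatingTable(make_table(rows))


class TestTestRetest:
    def test_perfect_duplication(self):
        table = _session_with_pairs([(1, 1), (4, 4), (7, 7)])
        rr = retest_corr(table)
        assert rr.loc["s1", "r"] == pytest.approx(1.0)

    def test_hand_computed_negative(self):
        table = _session_with_pairs([(1, 7), (7, 1), (4, 4)])
        rr = retest_corr(table)
        assert rr.loc["s1", "r"] == pytest.approx(-1.0)

    def test_constant_main_is_undefined(self):
        table = _session_with_pairs([(4, 1), (4, 4), (4, 7)])
        rr = retest_corr(table)
        assert np.isnan(rr.loc["s1", "r"])

    def test_too_few_pairs_undefined(self):
        table = _session_with_pairs([(1, 2), (3, 4)])
        assert np.isnan(retest_corr(table, min_pairs=3).loc["s1", "r"])

    def test_noiseless_synthetic_is_exactly_one(self):
        truth = default_truth("narrative", seed=3)
        truth.n_stimuli = 25
        truth.rater.noise_sd = 0.0
        truth.rater.bias_sd = 0.0
        truth.rater.n_raters = 3
        rr = retest_corr(generate_rater_ratings(truth))
        assert np.allclose(rr["r"].dropna(), 1.0)


class TestSplitHalf:
    def test_fixed_seed_reproducible(self, small_rater_table):
        a = split_half(small_rater_table, n_rep=10, seed=5)
        b = split_half(small_rater_table, n_rep=10, seed=5)
        assert np.array_equal(a["r"].to_numpy(), b["r"].to_numpy())

    def test_matches_closed_form(self):
        """Signal variance 1, noise variance 1, halves of 10 raters:
        the correlation of two half-mean vectors is 1/(1 + 1/10)."""
        truth = default_truth("narrative", seed=21)
        truth.n_stimuli = 200
        truth.scale_ids = truth.scale_ids[:4]
        truth.loadings = truth.loadings[:4]
        truth.uniqueness = truth.uniqueness[:4]
        truth.gain = 0.45  # keeps the signal clear of the slider bounds
        truth.rater.n_raters = 20
        truth.rater.bias_sd = 0.0
        truth.rater.noise_sd = 0.45  # noise sd = signal sd
        table = generate_rater_ratings(truth)
        sh = split_half(table, n_rep=50, seed=3)
        expected = 1.0 / (1.0 + 1.0 / 10.0)
        assert sh["r"].mean() == pytest.approx(expected, abs=0.05)

    def test_spearman_brown_monotone_in_raters(self):
        means = []
        for n_raters in (4, 10, 20):
            truth = default_truth("narrative", seed=31)
            truth.n_stimuli = 120
            truth.scale_ids = truth.scale_ids[:3]
            truth.loadings = truth.loadings[:3]
            truth.uniqueness = truth.uniqueness[:3]
            truth.gain = 0.5
            truth.rater.n_raters = n_raters
            truth.rater.noise_sd = 0.8
            sh = split_half(generate_rater_ratings(truth), n_rep=20, seed=1)
            means.append(sh["r"].mean())
        assert means[0] < means[1] < means[2]


class TestFlagging:
    def test_explicit_roster_leaves_23_of_28(self):
        import pandas as pd
        from emospace.reliability import ScaleQualityReport

        scales = [f"scale_{i}" for i in range(23)] + list(DEFAULT_LOW_QUALITY_SCALES)
        report = ScaleQualityReport(
            summary=pd.DataFrame(
                {"retest_r": 0.6, "split_half_r": 0.8, "n_sessions": 20},
                index=pd.Index(scales, name="scale_id"),
            )
        )
        flagged = flag_low_quality(report, explicit=DEFAULT_LOW_QUALITY_SCALES)
        assert flagged == set(DEFAULT_LOW_QUALITY_SCALES)
        assert len(set(scales) - flagged) == 23

    def test_threshold_rule_flags_only_low_scale(self):
        import pandas as pd
        from emospace.reliability import ScaleQualityReport

        report = ScaleQualityReport(
            summary=pd.DataFrame(
                {"retest_r": [0.5, 0.0, 0.6], "split_half_r": 0.8,
                 "n_sessions": 10},
                index=pd.Index(["a", "b", "c"], name="scale_id"),
            )
        )
        assert flag_low_quality(report, retest_threshold=0.2) == {"b"}

    def test_all_above_thresholds_empty(self, small_rater_table):
        report = scale_quality(small_rater_table, n_rep=5, seed=0)
        assert flag_low_quality(report, retest_threshold=0.0) == set()


class TestReadability:
    def test_hand_counted_sentence(self):
        # "The cat sat on the mat.": 6 words, 1 sentence, 6 syllables
        assert fk_grade("The cat sat on the mat.") == pytest.approx(
            0.39 * 6 + 11.8 * 1.0 - 15.59, abs=1e-10
        )

    def test_formula_evaluation(self):
        # words/sentences = 12, syllables/words = 1.5 -> 6.79
        text = (
            "The happy dog sat on the little mat "
            "under wooden tables today."
        )
        words = 12
        syll = sum(count_syllables(w) for w in text.replace(".", "").split())
        assert syll / words == pytest.approx(1.5)
        assert fk_grade(text) == pytest.approx(0.39 * 12 + 11.8 * 1.5 - 15.59)

    def test_doubling_text_leaves_grade_unchanged(self):
        text = "Feeling afraid of immediate danger. It can be mild or strong."
        assert fk_grade(text) == pytest.approx(fk_grade(text + " " + text))

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            fk_grade("...")
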