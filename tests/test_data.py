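"""Rating-table IO, validation, exclusion rules, and aggregation."""

import numpy as np
import pandas as pd
import pytest

from emospace.data import (
    ExclusionRules,
    RatingTable,
    SchemaError,
    ValidationError,
    aggregate_matrix,
    apply_exclusions,
    read_rating_table,
    write_rating_table,
)
from conftest import make_table


def _toy(ratings=(1.0, 4.0, 7.0)):
    return make_table(
        [
            ("p1", "s1", "narrative", f"stim{i}", "happy", r, "main")
            for i, r in enumerate(ratings)
        ]
    )


class TestValidation:
    def test_boundary_ratings_accepted(self):
        table = RatingTable(_toy((1.0, 4.0, 7.0)))
        assert len(table) == 3

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            RatingTable(_toy((1.0, 4.0, 8.0)))

    def test_duplicate_key_rejected(self):
        df = _toy()
        df.loc[1, "stimulus_id"] = "stim0"
        with pytest.raises(ValidationError, match="duplicated"):
            RatingTable(df)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="rating"):
            RatingTable(_toy().drop(columns=["rating"]))

    def test_orphan_retest_rejected(self):
        df = make_table(
            [
                ("p1", "s1", "narrative", "a", "happy", 3.0, "main"),
                ("p1", "s1", "narrative", "b", "happy", 3.0, "retest"),
            ]
        )
        with pytest.raises(ValidationError, match="retest"):
            RatingTable(df)


class TestIO:
    def test_roundtrip_preserves_records(self, tmp_path, small_rater_table):
        path = tmp_path / "ratings.csv"
        write_rating_table(small_rater_table, path)
        back = read_rating_table(path)
        a = small_rater_table.records.sort_values(
            ["session_id", "stimulus_id", "trial_type"]
        ).reset_index(drop=True)
        b = back.records.sort_values(
            ["session_id", "stimulus_id", "trial_type"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[b.columns], b, check_dtype=False)

    def test_column_mapping(self, tmp_path):
        df = _toy().rename(columns={"participant_id": "subj"})
        path = tmp_path / "mapped.csv"
        df.to_csv(path, index=False)
        table = read_rating_table(path, column_map={"subj": "participant_id"})
        assert table.n_participants == 1


class TestExclusions:
    def test_fast_trial_dropped_with_reason(self):
        # 20-trial session: a single 300 ms trial stays under the 10%
        # invalid-fraction session rule, so only that trial is dropped
        df = make_table(
            [
                ("p1", "s1", "narrative", f"st{i}", "happy", 4.0, "main")
                for i in range(20)
            ]
        )
        df.loc[0, "reaction_time_ms"] = 300.0
        out, rep = apply_exclusions(RatingTable(df))
        assert rep.trials_dropped["rt_min"] == 1
        assert len(out) == 19

    def test_two_failed_attention_checks_drop_session(self):
        df = _toy()
        df["attention_fails"] = 2
        out, rep = apply_exclusions(RatingTable(df))
        assert rep.sessions_dropped["attention"] == 1
        assert len(out) == 0

    def test_one_failed_check_is_tolerated(self):
        df = _toy()
        df["attention_fails"] = 1
        out, rep = apply_exclusions(RatingTable(df))
        assert len(out) == 3

    def test_clean_table_is_noop(self):
        df = make_table(
            [
                ("p1", "s1", "narrative", f"st{i}", "happy", 4.0 + (i % 3), "main")
                for i in range(12)
            ]
        )
        out, rep = apply_exclusions(RatingTable(df))
        assert len(out) == 12
        assert all(v == 0 for v in rep.trials_dropped.values())
        assert all(v == 0 for v in rep.sessions_dropped.values())
        assert all(v == 0 for v in rep.participants_dropped.values())

    def test_idempotent(self, small_rater_table):
        table = small_rater_table
        df = table.records.copy()
        df.loc[df.index[:50], "reaction_time_ms"] = 100.0
        once, _ = apply_exclusions(RatingTable(df, validate=False))
        twice, rep2 = apply_exclusions(once)
        assert len(twice) == len(once)
        assert all(v == 0 for v in rep2.trials_dropped.values())

    def test_invalid_trial_fraction_drops_session(self):
        rows = [
            ("p1", "s1", "narrative", f"st{i}", "happy", 4.0, "main",
             100.0 if i < 2 else 2000.0, 0)
            for i in range(10)
        ]
        out, rep = apply_exclusions(RatingTable(make_table(rows)))
        # 2 of 10 trials invalid > 10%
        assert rep.sessions_dropped["invalid_trials"] == 1
        assert len(out) == 0

    def test_counts_reconcile(self, small_rater_table):
        df = small_rater_table.records.copy()
        df.loc[df.index[:30], "reaction_time_ms"] = 50.0
        table = RatingTable(df, validate=False)
        out, rep = apply_exclusions(table)
        dropped_sessions = sum(rep.sessions_dropped.values())
        assert rep.n_sessions_in - dropped_sessions >= rep.n_sessions_out
        assert rep.n_trials_in == len(table)


class TestAggregation:
    def test_mean_over_raters(self):
        rows = [
            ("p1", "s1", "narrative", "st", "happy", 3.0, "main"),
            ("p2", "s2", "narrative", "st", "happy", 5.0, "main"),
        ]
        mat = aggregate_matrix(RatingTable(make_table(rows)), "narrative")
        assert mat.values.loc["st", "happy"] == 4.0

    def test_retest_excluded_from_means(self):
        rows = [
            ("p1", "s1", "narrative", "st", "happy", 3.0, "main"),
            ("p1", "s1", "narrative", "st", "happy", 7.0, "retest"),
        ]
        mat = aggregate_matrix(RatingTable(make_table(rows)), "narrative")
        assert mat.values.loc["st", "happy"] == 3.0

    def test_real_life_passthrough(self):
        rows = [
            ("p1", f"s{i}", "real_life", f"inst{i}", sc, float(1 + (i + j) % 7),
             "main")
            for i in range(10)
            for j, sc in enumerate(["a", "b", "c"])
        ]
        mat = aggregate_matrix(RatingTable(make_table(rows)), "real_life")
        assert mat.shape == (10, 3)
        assert mat.aggregation == "single-rater"

    def test_missing_cell_reported(self):
        rows = [
            ("p1", "s1", "narrative", "st1", "happy", 3.0, "main"),
            ("p1", "s1", "narrative", "st2", "sad", 3.0, "main"),
        ]
        with pytest.raises(ValidationError, match="cell"):
            aggregate_matrix(RatingTable(make_table(rows)), "narrative")

    def test_cell_within_contributing_ratings(self, small_rater_table):
        mat = aggregate_matrix(small_rater_table, "narrative")
        main = small_rater_table.main_trials()
        lo = main.groupby(["stimulus_id", "scale_id"])["rating"].min().unstack()
        hi = main.groupby(["stimulus_id", "scale_id"])["rating"].max().unstack()
        v = mat.values
        assert ((v >= lo[v.columns] - 1e-12) & (v <= hi[v.columns] + 1e-12)).all().all()
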