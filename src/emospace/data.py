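"""Core domain containers and trial/session/participant screening.

The raw unit of every reliability and exclusion computation is the
:class:`RatingTable`: long-format trial records, one row per
(participant, session, stimulus, scale, trial type) with a slider rating
in [1, 7].  Multivariate analyses operate on the :class:`RatingMatrix`,
a stimulus-by-scale aggregate (rater means for evoked domains, raw
single-rater rows for real-life experience sampling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RATING_MIN",
    "RATING_MAX",
    "RatingTable",
    "RatingMatrix",
    "ScaleDefinition",
    "ExclusionRules",
    "ExclusionReport",
    "SchemaError",
    "ValidationError",
    "read_rating_table",
    "write_rating_table",
    "apply_exclusions",
    "aggregate_matrix",
]

RATING_MIN = 1.0
RATING_MAX = 7.0

#: required columns of a long-format rating table
REQUIRED_COLUMNS = (
    "participant_id",
    "session_id",
    "domain",
    "stimulus_id",
    "scale_id",
    "rating",
    "trial_type",
)
#: optional columns (filled with NaN / 0 when absent)
OPTIONAL_COLUMNS = ("reaction_time_ms", "attention_fails", "wave")

DOMAINS = ("narrative", "video", "real_life")
TRIAL_TYPES = ("main", "retest")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """Record-level invariant violated (range, uniqueness, referencing)."""


@dataclass
class RatingTable:
    """Long-format trial-level ratings.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per trial.  Must carry :data:`REQUIRED_COLUMNS`;
        :data:`OPTIONAL_COLUMNS` are added (empty) if missing.
    validate : bool
        Check invariants on construction (default True).
    """

    records: pd.DataFrame
    validate: bool = True

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = df.copy()
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = 0 if col == "attention_fails" else np.nan
        df["rating"] = pd.to_numeric(df["rating"])
        df["reaction_time_ms"] = pd.to_numeric(df["reaction_time_ms"])
        df = df.reset_index(drop=True)
        self.records = df
        if self.validate:
            self._check_invariants()

    def _check_invariants(self) -> None:
        df = self.records
        bad_domain = set(df["domain"].unique()) - set(DOMAINS)
        if bad_domain:
            raise ValidationError(f"unknown domain value(s): {sorted(bad_domain)}")
        bad_type = set(df["trial_type"].unique()) - set(TRIAL_TYPES)
        if bad_type:
            raise ValidationError(f"unknown trial_type value(s): {sorted(bad_type)}")
        out = df.index[(df["rating"] < RATING_MIN) | (df["rating"] > RATING_MAX)]
        if len(out):
            rows = df.loc[out[:20], ["session_id", "stimulus_id", "scale_id", "rating"]]
            raise ValidationError(
                f"{len(out)} rating(s) outside [{RATING_MIN:g}, {RATING_MAX:g}]; "
                f"first offending rows:\n{rows.to_string()}"
            )
        key = ["session_id", "stimulus_id", "scale_id", "trial_type"]
        dup = df.duplicated(subset=key)
        if dup.any():
            rows = df.loc[dup, key].head(20)
            raise ValidationError(
                f"{int(dup.sum())} duplicated (session, stimulus, scale, trial_type) "
                f"key(s); first offenders:\n{rows.to_string()}"
            )
        retest = df[df["trial_type"] == "retest"]
        if len(retest):
            main_keys = set(
                map(
                    tuple,
                    df.loc[
                        df["trial_type"] == "main",
                        ["session_id", "stimulus_id", "scale_id"],
                    ].itertuples(index=False),
                )
            )
            orphan = [
                t
                for t in retest[["session_id", "stimulus_id", "scale_id"]].itertuples(
                    index=False
                )
                if tuple(t) not in main_keys
            ]
            if orphan:
                raise ValidationError(
                    f"{len(orphan)} retest trial(s) without a matching main trial; "
                    f"first: {orphan[:5]}"
                )

    # -- convenience -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_participants(self) -> int:
        return self.records["participant_id"].nunique()

    @property
    def n_sessions(self) -> int:
        return self.records["session_id"].nunique()

    def main_trials(self) -> pd.DataFrame:
        return self.records[self.records["trial_type"] == "main"]

    def retest_pairs(self) -> pd.DataFrame:
        """Paired (main, retest) ratings, one row per retested trial.

        Returns a frame with columns session_id, scale_id, stimulus_id,
        rating_main, rating_retest.
        """
        df = self.records
        key = ["session_id", "stimulus_id", "scale_id"]
        main = df[df["trial_type"] == "main"][key + ["rating"]]
        retest = df[df["trial_type"] == "retest"][key + ["rating"]]
        pairs = main.merge(retest, on=key, suffixes=("_main", "_retest"))
        return pairs


@dataclass
class RatingMatrix:
    """Stimulus/instance-by-scale aggregate ratings.

    ``values`` is a DataFrame indexed by stimulus (or instance) id with
    one column per scale; ``aggregation`` records whether cells are
    rater means ("rater-mean") or raw single-rater rows ("single-rater").
    """

    values: pd.DataFrame
    domain: str
    aggregation: str = "rater-mean"
    row_labels: pd.Series | None = None  # intended emotion category per row

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValidationError(f"missing cells after aggregation in scales {bad}")
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}")
        if self.row_labels is not None:
            self.row_labels = self.row_labels.reindex(self.values.index)

    @property
    def scales(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stimuli(self) -> list:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def restrict(self, scales: Sequence[str]) -> "RatingMatrix":
        """Column subset in the given order."""
        return RatingMatrix(
            self.values[list(scales)],
            domain=self.domain,
            aggregation=self.aggregation,
            row_labels=self.row_labels,
        )


@dataclass
class ScaleDefinition:
    """A rating scale with its definition text and readability grade."""

    scale_id: str
    definition: str
    family: str = "affective"  # basic-emotion | affective | biological
    grade: float | None = None

    def __post_init__(self) -> None:
        if not self.definition.strip():
            raise ValidationError(f"scale {self.scale_id}: empty definition")


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------


@dataclass
class ExclusionRules:
    """Trial/session/participant screening thresholds.

    Defaults follow the standard screen for slider-rating experiments:
    trials are invalid when timed out or answered in under 400 ms;
    sessions are invalid on more than one failed attention check (of 3),
    on retest reliability more than 3 SD below the mean of the same
    (scale, stimulus-set) rater cohort, or on more than 10% invalid
    trials; participants are dropped after more than 3 invalid sessions.
    """

    rt_min_ms: float = 400.0
    max_attention_fails: int = 1
    reliability_sd: float = 3.0
    max_invalid_trial_frac: float = 0.10
    max_invalid_sessions: int = 3
    min_retest_pairs: int = 3


@dataclass
class ExclusionReport:
    """Per-rule tallies of dropped trials, sessions, and participants."""

    n_trials_in: int = 0
    n_sessions_in: int = 0
    n_participants_in: int = 0
    trials_dropped: dict = field(default_factory=dict)
    sessions_dropped: dict = field(default_factory=dict)
    participants_dropped: dict = field(default_factory=dict)
    n_trials_out: int = 0
    n_sessions_out: int = 0
    n_participants_out: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def apply_exclusions(
    table: RatingTable, rules: ExclusionRules | None = None
) -> tuple[RatingTable, ExclusionReport]:
    """Screen trials, sessions, and participants.

    Order of operations: invalid trials are flagged (timeout or
    RT < ``rt_min_ms``); sessions are dropped for attention-check
    failures, for low within-session test-retest reliability relative to
    the same-scale/same-stimulus-set cohort (mean - ``reliability_sd``
    * SD, strict <), or for more than ``max_invalid_trial_frac`` invalid
    trials; finally participants with more than ``max_invalid_sessions``
    invalid sessions are removed entirely.  The surviving table has the
    flagged invalid trials removed.

    Returns the screened table and an :class:`ExclusionReport` whose
    per-level drop counts plus survivors reconcile with the input.
    """
    rules = rules or ExclusionRules()
    df = table.records.copy()
    rep = ExclusionReport(
        n_trials_in=len(df),
        n_sessions_in=df["session_id"].nunique(),
        n_participants_in=df["participant_id"].nunique(),
    )

    rt = df["reaction_time_ms"]
    invalid_rt = rt.notna() & (rt < rules.rt_min_ms)
    if "timed_out" in df.columns:
        invalid_timeout = df["timed_out"].fillna(False).astype(bool)
    else:
        invalid_timeout = pd.Series(False, index=df.index)
    invalid_trial = invalid_rt | invalid_timeout
    rep.trials_dropped["rt_min"] = int(invalid_rt.sum())
    rep.trials_dropped["timeout"] = int((invalid_timeout & ~invalid_rt).sum())

    # --- session-level rules (computed before removing invalid trials,
    #     because the invalid-trial fraction refers to the session's trials)
    by_sess = df.groupby("session_id")
    sess_info = pd.DataFrame(
        {
            "participant_id": by_sess["participant_id"].first(),
            "attention_fails": by_sess["attention_fails"].max(),
            "invalid_frac": invalid_trial.groupby(df["session_id"]).mean(),
            "scale_id": by_sess["scale_id"].first(),
            "domain": by_sess["domain"].first(),
        }
    )

    drop_attention = sess_info["attention_fails"] > rules.max_attention_fails
    drop_frac = sess_info["invalid_frac"] > rules.max_invalid_trial_frac

    # retest reliability within (scale, domain) cohorts, on valid trials only
    from .reliability import test_retest  # local import to avoid a cycle

    valid_table = RatingTable(df[~invalid_trial], validate=False)
    rr = test_retest(valid_table, min_pairs=rules.min_retest_pairs)
    drop_rel = pd.Series(False, index=sess_info.index)
    if len(rr):
        rr = rr.drop(columns="scale_id").join(
            sess_info[["scale_id", "domain"]], how="left"
        )
        for _, grp in rr.groupby(["scale_id", "domain"]):
            r = grp["r"].dropna()
            if len(r) >= 2 and r.std(ddof=1) > 0:
                cut = r.mean() - rules.reliability_sd * r.std(ddof=1)
                low = r.index[r < cut]
                drop_rel.loc[low] = True

    drop_sess = drop_attention | drop_frac | drop_rel
    rep.sessions_dropped["attention"] = int(drop_attention.sum())
    rep.sessions_dropped["low_reliability"] = int((drop_rel & ~drop_attention).sum())
    rep.sessions_dropped["invalid_trials"] = int(
        (drop_frac & ~drop_attention & ~drop_rel).sum()
    )

    # --- participant level
    invalid_sess_per_part = (
        drop_sess.groupby(sess_info["participant_id"]).sum().astype(int)
    )
    drop_part = invalid_sess_per_part[
        invalid_sess_per_part > rules.max_invalid_sessions
    ].index
    rep.participants_dropped["invalid_sessions"] = len(drop_part)

    keep = (
        ~invalid_trial
        & ~df["session_id"].map(drop_sess).fillna(False).astype(bool)
        & ~df["participant_id"].isin(drop_part)
    )
    out = RatingTable(df[keep], validate=False)
    rep.n_trials_out = len(out)
    rep.n_sessions_out = out.records["session_id"].nunique()
    rep.n_participants_out = out.records["participant_id"].nunique()
    return out, rep


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_matrix(table: RatingTable, domain: str) -> RatingMatrix:
    """Build the stimulus-by-scale matrix for one domain.

    Evoked domains (narrative, video): each cell is the mean of all main
    trials (retests never enter the mean) across raters of that
    (stimulus, scale).  Real-life: one row per instance, ratings passed
    through untouched (instances are idiosyncratic, so averaging across
    participants is not meaningful).
    """
    df = table.records
    df = df[(df["domain"] == domain) & (df["trial_type"] == "main")]
    if df.empty:
        raise ValidationError(f"no main trials for domain {domain!r}")
    if domain == "real_life":
        wide = df.pivot_table(
            index="stimulus_id", columns="scale_id", values="rating", aggfunc="first"
        )
        agg = "single-rater"
    else:
        wide = df.pivot_table(
            index="stimulus_id", columns="scale_id", values="rating", aggfunc="mean"
        )
        agg = "rater-mean"
    if wide.isna().any().any():
        missing = [
            (s, c)
            for s in wide.index
            for c in wide.columns[wide.loc[s].isna()]
        ]
        raise ValidationError(
            f"empty (stimulus, scale) cell(s): {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    wide.columns.name = None
    wide.index.name = "stimulus_id"
    return RatingMatrix(wide, domain=domain, aggregation=agg)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_rating_table(
    path,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> RatingTable:
    """Read a delimited long-format rating table.

    ``column_map`` renames file columns to the canonical schema, e.g.
    ``{"subj": "participant_id"}``.  Out-of-range ratings and duplicate
    keys raise :class:`ValidationError` listing the offending rows; a
    missing required column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return RatingTable(df)


def write_rating_table(table: RatingTable, path, sep: str = ",") -> None:
    """Write a rating table; a later :func:`read_rating_table` round-trips."""
    table.records.to_csv(path, sep=sep, index=False)
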