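"""Scale-quality metrics: test-retest, split-half, and readability.

Within-subject consistency is measured per session as the Pearson
correlation between the main-trial ratings and their retest repeats.
Between-subject consensus is measured per scale by split-half
reliability: raters of the same (scale, stimulus set) are split at
random, stimulus means are computed per half, and the two mean vectors
are correlated; the split is repeated (50 times by default).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import RatingTable

__all__ = [
    "test_retest",
    "split_half",
    "ScaleQualityReport",
    "scale_quality",
    "flag_low_quality",
    "count_syllables",
    "fk_grade",
    "readability_reliability_corr",
    "DEFAULT_LOW_QUALITY_SCALES",
]

#: scales conventionally screened out for low quality in the 28-scale roster
DEFAULT_LOW_QUALITY_SCALES = (
    "self_relevance",
    "intrinsic_extrinsic",
    "remembering",
    "mental_bodily",
    "future",
)


def test_retest(table: RatingTable, min_pairs: int = 3) -> pd.DataFrame:
    """Per-session test-retest Pearson correlation.

    Returns a DataFrame indexed by session_id with columns ``r`` (NaN
    when fewer than ``min_pairs`` pairs or either vector is constant),
    ``n_pairs``, and ``scale_id``.
    """
    pairs = table.retest_pairs()
    if pairs.empty:
        warnings.warn("no retest trials; test-retest reliability is empty")
        return pd.DataFrame(columns=["r", "n_pairs", "scale_id"])
    rows = {}
    for sess, grp in pairs.groupby("session_id"):
        a = grp["rating_main"].to_numpy(float)
        b = grp["rating_retest"].to_numpy(float)
        if len(a) < min_pairs or np.std(a) == 0 or np.std(b) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        rows[sess] = {"r": r, "n_pairs": len(a), "scale_id": grp["scale_id"].iloc[0]}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "session_id"
    return out


def split_half(
    table: RatingTable,
    n_rep: int = 50,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Split-half reliability per (scale, domain) cohort.

    For each repetition the raters (sessions) of a cohort are split at
    random into two halves; per-stimulus mean ratings (main trials) are
    computed within each half and the two mean vectors are Pearson-
    correlated.  Returns a long DataFrame with columns scale_id, domain,
    rep, r, n_raters.
    """
    rng = np.random.default_rng(seed)
    df = table.main_trials()
    out = []
    for (scale, domain), grp in df.groupby(["scale_id", "domain"]):
        wide = grp.pivot_table(
            index="stimulus_id", columns="session_id", values="rating"
        )
        n_raters = wide.shape[1]
        if n_raters < 2:
            continue
        if n_raters < 4:
            warnings.warn(
                f"scale {scale!r} ({domain}): only {n_raters} raters; "
                "split halves have size < 2"
            )
        cols = np.arange(n_raters)
        half = n_raters // 2
        arr = wide.to_numpy(float)
        for rep in range(n_rep):
            perm = rng.permutation(cols)
            a = np.nanmean(arr[:, perm[:half]], axis=1)
            b = np.nanmean(arr[:, perm[half:]], axis=1)
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            out.append(
                {"scale_id": scale, "domain": domain, "rep": rep, "r": r,
                 "n_raters": n_raters}
            )
    return pd.DataFrame(out)


@dataclass
class ScaleQualityReport:
    """Median reliabilities per scale plus the excluded-scale flags."""

    summary: pd.DataFrame  # index scale_id: retest_r, split_half_r, n_sessions
    excluded: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.summary.copy()
        out["excluded"] = out.index.isin(self.excluded)
        return out


def scale_quality(
    table: RatingTable, n_rep: int = 50, seed: int = 0
) -> ScaleQualityReport:
    """Median test-retest and split-half reliability per scale.

    Medians ignore sessions/splits with undefined correlations (rather
    than coding them 0).
    """
    rr = test_retest(table)
    sh = split_half(table, n_rep=n_rep, seed=seed)
    retest_med = rr.groupby("scale_id")["r"].median()
    n_sess = rr.groupby("scale_id")["r"].count()
    sh_med = (
        sh.groupby("scale_id")["r"].median()
        if len(sh)
        else pd.Series(dtype=float)
    )
    summary = pd.DataFrame(
        {"retest_r": retest_med, "split_half_r": sh_med, "n_sessions": n_sess}
    )
    summary.index.name = "scale_id"
    return ScaleQualityReport(summary=summary)


def flag_low_quality(
    report: ScaleQualityReport,
    explicit: list | tuple | None = None,
    retest_threshold: float | None = None,
    split_half_threshold: float | None = None,
) -> set:
    """Flag scales to exclude.

    Either pass ``explicit`` (a named roster, e.g.
    :data:`DEFAULT_LOW_QUALITY_SCALES`) or numeric thresholds; scales
    whose median reliability falls strictly below a given threshold are
    flagged.  The flags are also recorded on the report.
    """
    flagged: set = set()
    if explicit is not None:
        # a named roster is honored as-is, present in the data or not
        flagged |= set(explicit)
    if retest_threshold is not None:
        low = report.summary.index[report.summary["retest_r"] < retest_threshold]
        flagged |= set(low)
    if split_half_threshold is not None:
        low = report.summary.index[
            report.summary["split_half_r"] < split_half_threshold
        ]
        flagged |= set(low)
    report.excluded = sorted(flagged)
    return flagged


# ---------------------------------------------------------------------------
# Readability
# ---------------------------------------------------------------------------

_VOWEL_GROUP = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Heuristic syllable count: vowel groups with a silent-e correction.

    Dictionary-free: counts maximal vowel runs (y counts as a vowel),
    subtracts a trailing silent 'e' (but not '-le' after a consonant),
    floor 1.
    """
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        return 0
    n = len(_VOWEL_GROUP.findall(w))
    if w.endswith("e") and not w.endswith(("le", "ee", "ye")) and n > 1:
        n -= 1
    return max(n, 1)


def fk_grade(text: str) -> float:
    """Flesch-Kincaid grade level of a text.

    0.39 * (words/sentences) + 11.8 * (syllables/words) - 15.59.
    Sentences are split on ``.!?;`` runs; tokens without letters are not
    words.  Raises ValueError on empty text.
    """
    sentences = [s for s in re.split(r"[.!?;]+", text) if re.search(r"[A-Za-z]", s)]
    words = [w for w in re.findall(r"[A-Za-z][A-Za-z'\-]*", text)]
    if not sentences or not words:
        raise ValueError("text has no sentences or no words")
    syllables = sum(count_syllables(w) for w in words)
    return 0.39 * len(words) / len(sentences) + 11.8 * syllables / len(words) - 15.59


def readability_reliability_corr(
    grades: pd.Series, report: ScaleQualityReport, which: str = "retest_r"
) -> tuple[float, float]:
    """Pearson correlation between scale readability grade and median
    reliability; returns (r, p).  Scales missing from either side are
    dropped."""
    joined = pd.concat([grades.rename("grade"), report.summary[which]], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 scales with both grade and reliability")
    r, p = stats.pearsonr(joined["grade"], joined[which])
    return float(r), float(p)
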