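"""Individual differences in mean rating magnitude.

Evoked-domain ratings are first centered per (stimulus, scale) across
participants, so a participant's session mean isolates their rating
bias from stimulus content.  Real-life means are taken across survey
waves, restricted to participants with complete data from all waves,
optionally corrected by the participant's evoked-rating baseline bias.
The association screen crosses every scale with every participant
variable: Pearson correlations for continuous traits, Welch's t test
for binary groups (group 1 minus group 0), with Bonferroni correction
over the whole grid.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import RatingTable

__all__ = [
    "center_by_stimulus",
    "participant_means",
    "association_screen",
]

log = logging.getLogger(__name__)


def center_by_stimulus(table: RatingTable) -> RatingTable:
    """Subtract each (stimulus, scale) cross-participant mean rating.

    Idempotent; singleton cells center to exactly 0 (logged).
    Centering uses main trials' means but is applied to all trials.
    """
    df = table.records.copy()
    means = (
        df[df["trial_type"] == "main"]
        .groupby(["stimulus_id", "scale_id"])["rating"]
        .transform("mean")
    )
    cell_means = (
        df[df["trial_type"] == "main"]
        .groupby(["stimulus_id", "scale_id"])["rating"]
        .agg(["mean", "size"])
    )
    n_single = int((cell_means["size"] == 1).sum())
    if n_single:
        log.info("%d singleton (stimulus, scale) cells center to 0", n_single)
    lookup = cell_means["mean"]
    key = pd.MultiIndex.from_frame(df[["stimulus_id", "scale_id"]])
    df["rating"] = df["rating"].to_numpy() - lookup.reindex(key).to_numpy()
    return RatingTable(df, validate=False)


def participant_means(
    table: RatingTable,
    domain: str,
    complete_waves: int = 15,
    baseline: pd.Series | None = None,
) -> pd.DataFrame:
    """Participant-by-scale mean ratings.

    Evoked domains: per session, the mean of the stimulus-centered main
    ratings (one session = one scale), assembled into a participant x
    scale frame.  Real-life: the mean across waves per scale, restricted
    to participants present in all ``complete_waves`` waves.  If
    ``baseline`` (a per-participant evoked bias, e.g. the mean over
    evoked scales) is given, it is subtracted from every cell.
    """
    df = table.records
    df = df[(df["domain"] == domain) & (df["trial_type"] == "main")]
    if domain == "real_life":
        waves_per_part = df.groupby("participant_id")["wave"].nunique()
        complete = waves_per_part[waves_per_part >= complete_waves].index
        if len(complete) == 0:
            log.warning("no participants with complete %d-wave data", complete_waves)
        df = df[df["participant_id"].isin(complete)]
        out = df.pivot_table(
            index="participant_id", columns="scale_id", values="rating",
            aggfunc="mean",
        )
    else:
        centered = center_by_stimulus(RatingTable(df, validate=False))
        cdf = centered.main_trials()
        out = cdf.pivot_table(
            index="participant_id", columns="scale_id", values="rating",
            aggfunc="mean",
        )
    out.columns.name = None
    if baseline is not None:
        out = out.sub(baseline.reindex(out.index), axis=0)
    return out


def association_screen(
    means: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    groups: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scale-by-variable association grid.

    Continuous traits: Pearson r and p.  Binary groups: Welch's t
    (mean of group 1 minus group 0) and p.  The Bonferroni family is
    the entire tested grid.  Returns a long DataFrame with columns
    scale, variable, kind, statistic, p, n, significant_raw,
    significant_bonferroni.
    """
    rows = []
    for scale in means.columns:
        y = means[scale]
        if traits is not None:
            for var in traits.columns:
                joined = pd.concat([y, traits[var]], axis=1).dropna()
                if len(joined) < 3:
                    continue
                r, p = stats.pearsonr(joined.iloc[:, 1], joined.iloc[:, 0])
                rows.append(
                    dict(scale=scale, variable=var, kind="pearson_r",
                         statistic=float(r), p=float(p), n=len(joined))
                )
        if groups is not None:
            for var in groups.columns:
                joined = pd.concat([y, groups[var]], axis=1).dropna()
                g1 = joined.loc[joined[var] == 1, scale]
                g0 = joined.loc[joined[var] == 0, scale]
                if len(g1) < 2 or len(g0) < 2:
                    log.info("group %s too small for scale %s; skipped", var, scale)
                    continue
                t, p = stats.ttest_ind(g1, g0, equal_var=False)
                rows.append(
                    dict(scale=scale, variable=var, kind="welch_t",
                         statistic=float(t), p=float(p), n=len(joined))
                )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = len(out)
    out["significant_raw"] = out["p"] < alpha
    out["significant_bonferroni"] = out["p"] < alpha / m
    return out
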