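"""Robustness of factor solutions to decimation of stimuli and scales.

Stimulus decimation: random subsets of shrinking size are re-factored
and compared to the full-set solution by Tucker congruence (orthogonal
Procrustes aligned).  Scale decimation: scales are removed one at a
time in order of redundancy (highest mean correlation with the
remaining scales), the model is refitted, and matched factor-score
correlations against the full solution are recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factor import ExploratoryFactorAnalysis, tucker_congruence, _as_frame
from .rsa import CorrelationStructure

__all__ = [
    "DecimationCurves",
    "decimate_stimuli",
    "redundancy_order",
    "decimate_scales",
    "null_congruence",
]

log = logging.getLogger(__name__)


@dataclass
class DecimationCurves:
    """Per-size (or per-step) factor-similarity statistics."""

    curves: pd.DataFrame     # long: size/step x factor -> similarity
    mode: str                # "stimuli" | "scales"
    k: int

    def mean_by_size(self) -> pd.DataFrame:
        return self.curves.pivot_table(
            index="size", columns="factor", values="similarity", aggfunc="mean"
        )


def decimate_stimuli(
    matrix,
    k: int,
    step: int,
    n_rand: int = 20,
    seed: int = 0,
    min_size: int | None = None,
) -> DecimationCurves:
    """Random-subsample robustness curves.

    At each reduced size (full size minus multiples of ``step``),
    ``n_rand`` random subsets are re-factored with EFA(k) and each
    factor's Tucker congruence against the full-set solution recorded.
    Stops when the size falls below ``min_size`` (default k + 2).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    df = _as_frame(matrix)
    n = len(df)
    min_size = max(k + 2, 5) if min_size is None else min_size
    rng = np.random.default_rng(seed)
    full = ExploratoryFactorAnalysis(df).fit(k)
    lam_full = full.loadings.to_numpy()
    rows = [
        {"size": n, "rep": 0, "factor": f"F{j + 1}", "similarity": 1.0}
        for j in range(k)
    ]
    size = n - step
    while size >= min_size:
        for rep in range(n_rand):
            idx = rng.choice(n, size=size, replace=False)
            try:
                res = ExploratoryFactorAnalysis(df.iloc[idx]).fit(k)
            except Exception as exc:  # degenerate subsample
                log.info("size %d rep %d skipped: %s", size, rep, exc)
                continue
            cong = tucker_congruence(lam_full, res.loadings.to_numpy())
            for j in range(k):
                rows.append(
                    {"size": size, "rep": rep, "factor": f"F{j + 1}",
                     "similarity": float(cong.phi[j])}
                )
        size -= step
    return DecimationCurves(curves=pd.DataFrame(rows), mode="stimuli", k=k)


def redundancy_order(corr: CorrelationStructure) -> list:
    """Scale-removal order by iterated redundancy.

    Repeatedly removes the scale with the highest mean correlation with
    the remaining scales (ties broken by scale id), recomputing the
    means on the shrunken matrix, until two scales remain.  Returns the
    removal order (most redundant first); the two survivors are not
    listed.
    """
    c = corr.corr.copy()
    if len(c) < 3:
        raise ValueError("need at least 3 scales")
    order = []
    while len(c) > 2:
        p = len(c)
        mean_r = (c.sum(axis=1) - 1.0) / (p - 1)  # exclude the unit diagonal
        top = mean_r.max()
        tied = sorted(mean_r.index[np.isclose(mean_r, top)])
        drop = tied[0]
        order.append(drop)
        c = c.drop(index=drop, columns=drop)
    return order


def decimate_scales(
    matrix,
    k: int,
    order: list | None = None,
    min_scales: int = 5,
) -> DecimationCurves:
    """Scale-removal robustness curves.

    Removes scales one by one in ``order`` (default: the redundancy
    ordering of this matrix's own correlation structure), refits
    EFA(k), and records the Pearson correlation between each full-set
    factor-score vector and its best-matching subset factor score
    (greedy maximal-|r| assignment, one-to-one, sign-aligned).  Stops
    at ``min_scales`` scales or when k would reach the scale count.
    """
    df = _as_frame(matrix)
    if order is None:
        from .rsa import scale_corr

        order = redundancy_order(scale_corr(df))
    full = ExploratoryFactorAnalysis(df).fit(k)
    full_scores = full.scores.to_numpy()
    rows = [
        {"size": df.shape[1], "step": 0, "factor": f"F{j + 1}", "similarity": 1.0}
        for j in range(k)
    ]
    remaining = list(df.columns)
    for step, scale in enumerate(order, start=1):
        remaining = [s for s in remaining if s != scale]
        if len(remaining) < max(min_scales, k + 1):
            break
        res = ExploratoryFactorAnalysis(df[remaining]).fit(k)
        sub_scores = res.scores.to_numpy()
        r = np.corrcoef(full_scores.T, sub_scores.T)[:k, k:]
        matched = _greedy_match(np.abs(r))
        for j, jj in matched:
            rows.append(
                {"size": len(remaining), "step": step, "factor": f"F{j + 1}",
                 "similarity": float(abs(r[j, jj]))}
            )
    return DecimationCurves(curves=pd.DataFrame(rows), mode="scales", k=k)


def _greedy_match(score: np.ndarray) -> list[tuple[int, int]]:
    """One-to-one greedy assignment maximizing |score| pair by pair."""
    score = score.copy()
    k = score.shape[0]
    pairs = []
    for _ in range(k):
        j, jj = np.unravel_index(np.nanargmax(score), score.shape)
        pairs.append((int(j), int(jj)))
        score[j, :] = -np.inf
        score[:, jj] = -np.inf
    return sorted(pairs)


def null_congruence(
    matrix, k: int, n_rep: int = 20, seed: int = 0
) -> np.ndarray:
    """Congruence baseline under destroyed structure.

    Each column of the matrix is independently row-permuted (breaking
    all between-scale covariance) and the EFA(k) solution of the
    scrambled data compared to the intact one; returns the pooled
    per-factor congruences over ``n_rep`` scrambles, the reference
    distribution for interpreting decimation curves.
    """
    df = _as_frame(matrix)
    rng = np.random.default_rng(seed)
    full = ExploratoryFactorAnalysis(df).fit(k)
    lam_full = full.loadings.to_numpy()
    out = []
    x = df.to_numpy(float)
    for _ in range(n_rep):
        xp = np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])
        try:
            res = ExploratoryFactorAnalysis(
                pd.DataFrame(xp, columns=df.columns)
            ).fit(k)
        except Exception:
            continue
        out.extend(tucker_congruence(lam_full, res.loadings.to_numpy()).phi)
    return np.asarray(out)
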