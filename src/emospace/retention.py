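"""How many factors to retain.

Six classical criteria — parallel analysis (PA), the optimal coordinate
(OC) and acceleration factor (AF) non-graphical scree rules, Very
Simple Structure (VSS, complexity 1), Velicer's minimum average partial
(MAP), and an empirical BIC over ML factor solutions — plus an
empirical split-half cross-validation: EFA on one half of the stimuli
proposes a loading pattern (|loading| > 0.2), a CFA with that pattern
is fitted to the other half, and the mean explained-variance and RMSEA
curves over k = 1..8 are inspected for an elbow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfa import ConfirmatoryFactorAnalysis
from .factor import ExploratoryFactorAnalysis, minres_extract, ml_extract, _as_frame

__all__ = [
    "scree_indices",
    "psych_indices",
    "RetentionReport",
    "cv_retention",
    "correlation_eigenvalues",
]


def correlation_eigenvalues(data) -> tuple[np.ndarray, int]:
    """Sorted (descending) eigenvalues of the column correlation matrix."""
    df = _as_frame(data)
    vals = np.linalg.eigvalsh(np.corrcoef(df.to_numpy(float), rowvar=False))
    return np.sort(vals)[::-1], len(df)


def scree_indices(
    eigenvalues: np.ndarray,
    n_obs: int,
    n_sim: int = 100,
    seed: int = 0,
    centile: float = 0.0,
) -> dict:
    """Non-graphical scree criteria on principal-component eigenvalues.

    PA: number of leading eigenvalues exceeding the rank-wise mean of
    eigenvalues of random normal data of the same size (``centile`` > 0
    compares against that percentile instead, a stricter null that is
    better calibrated on pure-noise data).  OC: number of
    leading eigenvalues exceeding their "optimal coordinate", the value
    predicted at rank i by the line through (i+1, e_{i+1}) and (p, e_p).
    AF: the rank preceding the sharpest change of slope (largest second
    difference), floored at 1.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    p = len(ev)
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be sorted in descending order")
    if n_obs <= p:
        raise ValueError("parallel analysis needs n_obs > n_scales")
    rng = np.random.default_rng(seed)
    rand_ev = np.empty((n_sim, p))
    for b in range(n_sim):
        x = rng.standard_normal((n_obs, p))
        rand_ev[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    if centile > 0:
        mean_rand = np.percentile(rand_ev, centile, axis=0)
    else:
        mean_rand = rand_ev.mean(axis=0)
    above = ev > mean_rand
    pa = int(np.argmin(above)) if not above.all() else p

    oc = 0
    for i in range(p - 2):  # ranks 1..p-2 (0-based i)
        x1, y1 = i + 2, ev[i + 1]
        x2, y2 = p, ev[p - 1]
        slope = (y2 - y1) / (x2 - x1) if x2 != x1 else 0.0
        pred = y1 + slope * ((i + 1) - x1)
        if ev[i] > pred:
            oc = i + 1
        else:
            break

    result = {"PA": pa, "OC": oc}
    if p < 3:
        warnings.warn("fewer than 3 eigenvalues: acceleration factor undefined")
        result["AF"] = None
        return result
    second = ev[2:] - 2.0 * ev[1:-1] + ev[:-2]  # indexed by rank 2..p-1
    af_rank = int(np.argmax(second)) + 2  # rank (1-based) of max curvature
    result["AF"] = max(af_rank - 1, 1)
    return result


def _map_index(corr: np.ndarray, k_max: int) -> int:
    """Velicer's minimum average partial criterion.

    Returns the k (1..k_max) minimizing the mean squared off-diagonal
    partial correlation after partialling out the first k principal
    components; degenerate no-structure input returns 1 by convention.
    """
    p = corr.shape[0]
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    maps = []
    mask = ~np.eye(p, dtype=bool)
    for k in range(1, min(k_max, p - 1) + 1):
        lam = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
        cstar = corr - lam @ lam.T
        d = np.sqrt(np.clip(np.diag(cstar), 1e-12, None))
        partial = cstar / np.outer(d, d)
        maps.append(float((partial[mask] ** 2).mean()))
    maps = np.asarray(maps)
    if not np.isfinite(maps).any():
        return 1
    return int(np.nanargmin(maps)) + 1


def _vss_index(corr: np.ndarray, k_max: int) -> int:
    """Very Simple Structure (complexity 1): keep only each scale's
    largest-|loading| entry and score how well the simplified model
    reproduces the off-diagonal correlations."""
    p = corr.shape[0]
    mask = ~np.eye(p, dtype=bool)
    denom = float((corr[mask] ** 2).sum())
    if denom == 0:  # no off-diagonal structure at all
        return 1
    fits = []
    for k in range(1, min(k_max, p - 2) + 1):
        lam, _ = minres_extract(corr, k)
        simple = np.zeros_like(lam)
        jmax = np.abs(lam).argmax(axis=1)
        simple[np.arange(p), jmax] = lam[np.arange(p), jmax]
        resid = corr - simple @ simple.T
        fits.append(1.0 - float((resid[mask] ** 2).sum()) / denom)
    return int(np.argmax(fits)) + 1


def _ebic_index(corr: np.ndarray, n_obs: int, k_max: int) -> int:
    """Empirical BIC: argmin over k of chi2_k - df_k * ln(n) for the
    ML k-factor solution (only k with positive df considered)."""
    best_k, best = 1, np.inf
    for k in range(1, k_max + 1):
        p = corr.shape[0]
        df = ((p - k) ** 2 - (p + k)) / 2.0
        if df <= 0:
            break
        _, _, chi2, df = ml_extract(corr, k, n_obs)
        ebic = chi2 - df * np.log(n_obs)
        if ebic < best:
            best, best_k = ebic, k
    return best_k


def psych_indices(corr, n_obs: int, k_max: int = 8) -> dict:
    """VSS (complexity 1), Velicer MAP, and empirical BIC retain-k."""
    corr = np.asarray(getattr(corr, "corr", corr), dtype=float)
    if hasattr(corr, "to_numpy"):
        corr = corr.to_numpy()
    vals = np.linalg.eigvalsh(corr)
    if vals.min() <= 1e-10:
        warnings.warn("correlation matrix not positive definite; ridge-regularized")
        corr = corr + (1e-8 - vals.min()) * np.eye(corr.shape[0])
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return {
        "VSS": _vss_index(corr, k_max),
        "MAP": _map_index(corr, k_max),
        "eBIC": _ebic_index(corr, n_obs, k_max),
    }


# ---------------------------------------------------------------------------
# Empirical cross-validation
# ---------------------------------------------------------------------------


@dataclass
class RetentionReport:
    """Per-criterion suggested k plus the EFA/CFA cross-validation curves."""

    k_range: list
    explained_variance: pd.DataFrame  # iterations x k, EFA half
    rmsea: pd.DataFrame               # iterations x k, CFA half
    chosen_k: int = 0
    criteria: dict = field(default_factory=dict)
    n_invalid: int = 0

    @property
    def mean_curves(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "explained_variance": self.explained_variance.mean(),
                "rmsea": self.rmsea.mean(),
            }
        )


def _elbow(mean_rmsea: pd.Series, tol: float) -> int:
    """Largest k whose RMSEA improvement over k-1 exceeds ``tol``."""
    ks = list(mean_rmsea.index)
    chosen = ks[0]
    for prev, k in zip(ks, ks[1:]):
        if mean_rmsea[prev] - mean_rmsea[k] > tol:
            chosen = k
    return int(chosen)


def cv_retention(
    matrix,
    k_range=range(1, 9),
    n_iter: int = 20,
    cutoff: float = 0.2,
    seed: int = 0,
    elbow_tol: float = 0.01,
) -> RetentionReport:
    """EFA-to-CFA split-half cross-validation over candidate k.

    Per iteration the stimuli are split at random into two halves.  For
    each k, EFA (minres + oblimin) on half A yields the explained
    variance (mean communality) and a loading pattern: each scale is
    assigned to every factor whose |pattern loading| exceeds ``cutoff``
    (cross-loadings stay free in the CFA).  A CFA with that pattern
    (ML; unassigned loadings fixed at 0; factor correlations free) is
    fitted to half B and its RMSEA recorded.  A k whose pattern leaves
    some factor empty, or whose CFA has non-positive df or fails, is
    marked invalid for that iteration and excluded from the means.

    The chosen k is the elbow of the mean RMSEA curve: the largest k
    improving on k-1 by more than ``elbow_tol``.
    """
    df = _as_frame(matrix)
    x = df.to_numpy(float)
    n = len(x)
    k_range = list(k_range)
    if n < 2 * (max(k_range) + 2):
        warnings.warn("few rows for split-half retention CV; results unstable")
    rng = np.random.default_rng(seed)
    ev = np.full((n_iter, len(k_range)), np.nan)
    rm = np.full((n_iter, len(k_range)), np.nan)
    n_invalid = 0
    for it in range(n_iter):
        perm = rng.permutation(n)
        a, b = x[perm[: n // 2]], x[perm[n // 2 :]]
        model_a = ExploratoryFactorAnalysis(pd.DataFrame(a, columns=df.columns))
        corr_b = np.corrcoef(b, rowvar=False)
        for kk, k in enumerate(k_range):
            try:
                with warnings.catch_warnings():
                    # Heywood warnings are routine when overfactoring a half
                    warnings.simplefilter("ignore")
                    res_a = model_a.fit(k)
            except Exception:
                n_invalid += 1
                continue
            ev[it, kk] = float(res_a.communalities.mean())
            pattern = np.abs(res_a.loadings.to_numpy()) > cutoff
            if (~pattern.any(axis=0)).any():
                n_invalid += 1
                continue
            try:
                cfa = ConfirmatoryFactorAnalysis(corr_b, pattern, n_obs=len(b))
                if cfa.df <= 0:
                    n_invalid += 1
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = cfa.fit()
                rm[it, kk] = fit.rmsea
            except Exception:
                n_invalid += 1
    ev_df = pd.DataFrame(ev, columns=k_range)
    rm_df = pd.DataFrame(rm, columns=k_range)
    valid_k = [k for k in k_range if rm_df[k].notna().any()]
    report = RetentionReport(
        k_range=k_range,
        explained_variance=ev_df,
        rmsea=rm_df,
        n_invalid=n_invalid,
    )
    if valid_k:
        report.chosen_k = _elbow(rm_df[valid_k].mean(), elbow_tol)
    return report
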