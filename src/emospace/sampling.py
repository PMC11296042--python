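"""Stimulus-set sizing and maximum-variation subset selection.

The subset size is judged by a PCA plateau: for random subsets of
increasing size, the number of principal components needed to reach a
target share (80%) of total variance grows and then plateaus; the
plateau size is the smallest size whose mean PC count comes within a
tolerance of the full-set value.  The subset itself is chosen by
maximum-variation sampling: greedy growth (each new stimulus maximizes
the summed Euclidean distance to those already selected) restarted
from every possible initial stimulus, keeping the run with the largest
total pairwise distance sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .factor import _as_frame

__all__ = ["PlateauResult", "pca_plateau", "max_variation", "subset_objective"]


@dataclass
class PlateauResult:
    curve: pd.DataFrame       # per size: mean and sd of the required PC count
    plateau_size: int | None
    full_value: float
    var_target: float


def _n_pcs_for_variance(x: np.ndarray, var_target: float) -> int:
    xc = x - x.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(xc, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total == 0:
        return 0
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, var_target - 1e-12) + 1)


def pca_plateau(
    features,
    sizes,
    n_rep: int = 100,
    var_target: float = 0.80,
    tol: float = 0.5,
    seed: int = 0,
) -> PlateauResult:
    """PC-count curve over random subsets of increasing size.

    Per size, ``n_rep`` random subsets are drawn and the minimal number
    of PCs reaching ``var_target`` cumulative variance is averaged.
    The plateau is the smallest size whose mean is within ``tol`` PCs
    of the full-set value (None if no tested size qualifies).
    """
    if not 0 < var_target <= 1:
        raise ValueError("var_target must lie in (0, 1]")
    x = _as_frame(features).to_numpy(float)
    n = len(x)
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > n:
        raise ValueError("subset size exceeds number of stimuli")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        counts = [
            _n_pcs_for_variance(x[rng.choice(n, size=size, replace=False)], var_target)
            for _ in range(n_rep if size < n else 1)
        ]
        rows.append(
            {"size": size, "mean_pcs": float(np.mean(counts)),
             "sd_pcs": float(np.std(counts))}
        )
    curve = pd.DataFrame(rows).set_index("size")
    full_value = float(_n_pcs_for_variance(x, var_target))
    plateau = None
    for size in sizes:
        if abs(curve.loc[size, "mean_pcs"] - full_value) <= tol:
            plateau = size
            break
    return PlateauResult(
        curve=curve, plateau_size=plateau, full_value=full_value,
        var_target=var_target,
    )


def subset_objective(features, subset) -> float:
    """Total pairwise Euclidean distance within a subset."""
    df = _as_frame(features)
    sub = df.loc[list(subset)].to_numpy(float)
    return float(pdist(sub).sum())


def max_variation(features, m: int, criterion: str = "sum") -> list:
    """Maximally diverse m-stimulus subset.

    Greedy growth from every possible starting stimulus: each addition
    maximizes the summed distance to the already-selected set (or the
    minimum distance, with ``criterion='maxmin'``).  Among the runs,
    the subset with the largest total pairwise distance sum wins; all
    ties break lexicographically by stimulus id.
    """
    if m < 2:
        raise ValueError("need m >= 2")
    df = _as_frame(features)
    ids = [str(i) for i in df.index]
    order = np.argsort(ids)  # lexicographic preference for tie-breaks
    rank = np.empty(len(ids), dtype=int)
    rank[order] = np.arange(len(ids))
    x = df.to_numpy(float)
    n = len(x)
    if m > n:
        raise ValueError("m exceeds number of stimuli")
    dist = squareform(pdist(x))

    best_total, best_subset = -np.inf, None
    for start in range(n):
        selected = [start]
        mask = np.ones(n, dtype=bool)
        mask[start] = False
        acc = dist[start].copy()  # summed distance to selected set
        for _ in range(m - 1):
            crit = acc if criterion == "sum" else None
            if criterion == "maxmin":
                crit = np.min(dist[np.ix_(selected, np.arange(n))], axis=0)
            cand = np.where(mask)[0]
            vals = crit[cand]
            top = vals.max()
            tied = cand[vals >= top - 1e-12]
            pick = tied[np.argmin(rank[tied])]
            selected.append(int(pick))
            mask[pick] = False
            acc += dist[pick]
        total = float(dist[np.ix_(selected, selected)].sum() / 2.0)
        key = sorted(rank[selected])
        if total > best_total + 1e-12 or (
            abs(total - best_total) <= 1e-12
            and best_subset is not None
            and key < sorted(rank[best_subset])
        ):
            best_total, best_subset = total, selected
    return [df.index[i] for i in sorted(best_subset, key=lambda i: rank[i])]
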