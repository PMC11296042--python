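"""Two-dimensional manifold embedding of emotion instances.

UMAP reduces the stimulus-by-scale space to 2-D for visualization.
The neighborhood size — the key locality/globality trade-off — is
chosen by split-half cross-validation: fit on one half, map the held
out half, and score the held-out embedding by trustworthiness (local
neighborhood preservation) and the Spearman correlation of pairwise
Euclidean distances (global structure); the chosen size maximizes the
rank-sum of the two metrics across the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.manifold import trustworthiness as _sk_trustworthiness

from .factor import _as_frame

__all__ = ["EmbeddingResult", "trustworthiness", "select_neighbors", "embed"]


def trustworthiness(x, e, k_nn: int = 5) -> float:
    """Neighborhood-preservation score of an embedding in [0, 1].

    Penalizes points that enter the embedded k-nearest-neighborhood of
    a point despite being far from it in the original space; 1 means
    the embedded neighborhoods contain no intruders.
    """
    x = np.asarray(_as_frame(x), dtype=float)
    e = np.asarray(e, dtype=float)
    if len(x) != len(e):
        raise ValueError("row counts differ")
    if k_nn >= len(x) / 2:
        raise ValueError("k_nn must be < n/2")
    return float(_sk_trustworthiness(x, e, n_neighbors=k_nn))


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame               # instances x 2
    n_neighbors: int
    seed: int
    cv_metrics: pd.DataFrame | None = None   # per grid size: T, rho
    extras: dict = field(default_factory=dict)


def _umap_model(n_neighbors: int, seed: int):
    # deferred import: umap triggers numba compilation on first use
    import umap

    return umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        random_state=seed,
        n_jobs=1,
    )


def select_neighbors(
    matrix,
    grid=(5, 10, 15, 25, 50),
    n_split: int = 10,
    k_nn: int = 5,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated neighborhood-size selection.

    Per split and grid size: fit UMAP on a random half, transform the
    held-out half, and record the held-out trustworthiness and the
    Spearman rho between original and embedded pairwise distances.
    Returns (chosen size, per-size mean metrics); the choice maximizes
    the rank-sum of the two mean metrics (ties -> smaller size).
    """
    df = _as_frame(matrix)
    x = df.to_numpy(float)
    n = len(x)
    grid = [int(g) for g in grid]
    if max(grid) >= n / 2:
        raise ValueError("grid sizes must be < n/2")
    rng = np.random.default_rng(seed)
    rows = []
    for split in range(n_split):
        for attempt in range(5):
            perm = rng.permutation(n)
            test = x[perm[n // 2 :]]
            train = x[perm[: n // 2]]
            if train.std(axis=0).min() > 0 and test.std(axis=0).min() > 0:
                break
            warnings.warn("degenerate half (constant column); resplitting")
        for g in grid:
            model = _umap_model(g, seed=seed + split)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(train)
                emb = model.transform(test)
            t = trustworthiness(test, emb, k_nn=min(k_nn, len(test) // 2 - 1))
            rho = stats.spearmanr(pdist(test), pdist(emb)).statistic
            rows.append({"n_neighbors": g, "split": split, "T": t, "rho": rho})
    metrics = (
        pd.DataFrame(rows).groupby("n_neighbors")[["T", "rho"]].mean().loc[grid]
    )
    ranks = metrics.rank(method="average")
    chosen = int(ranks.sum(axis=1).idxmax())
    return chosen, metrics


def embed(
    matrix,
    n_neighbors: int = 15,
    seed: int = 0,
    factor_scores: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> EmbeddingResult:
    """2-D UMAP embedding; deterministic under a fixed seed.

    Optional factor scores and category labels are joined onto the
    coordinates for downstream coloring.
    """
    df = _as_frame(matrix)
    if len(df) < n_neighbors + 1:
        raise ValueError("need n >= n_neighbors + 1 rows")
    model = _umap_model(n_neighbors, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(df.to_numpy(float))
    out = pd.DataFrame(coords, index=df.index, columns=["umap1", "umap2"])
    if factor_scores is not None:
        out = out.join(factor_scores)
    if labels is not None:
        out["label"] = labels.reindex(df.index)
    return EmbeddingResult(coords=out, n_neighbors=int(n_neighbors), seed=seed)
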