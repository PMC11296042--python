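"""Representational similarity of scale-by-scale correlation structure.

First-order structure is the Pearson correlation matrix over stimuli;
second-order similarity between two domains is the Spearman rank
correlation of the Fisher-z-transformed lower triangles, tested by a
joint row/column permutation null (10,000 draws by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import RatingMatrix
from .factor import _as_frame

__all__ = [
    "CorrelationStructure",
    "SecondOrderResult",
    "scale_corr",
    "seriate",
    "second_order",
    "perm_test",
]

_Z_CLAMP = np.arctanh(1.0 - 1e-12)


@dataclass
class CorrelationStructure:
    """Scale-by-scale Pearson correlations with a display ordering."""

    corr: pd.DataFrame
    order: list | None = None

    def __post_init__(self) -> None:
        c = self.corr.to_numpy()
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.abs(c).max() > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def scales(self) -> list:
        return list(self.corr.columns)

    def restrict(self, scales) -> "CorrelationStructure":
        scales = list(scales)
        return CorrelationStructure(self.corr.loc[scales, scales])

    def lower_triangle(self) -> np.ndarray:
        c = self.corr.to_numpy()
        i, j = np.tril_indices_from(c, k=-1)
        return c[i, j]


@dataclass
class SecondOrderResult:
    """Second-order Spearman similarity with (optional) permutation p."""

    rho: float
    p: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def scale_corr(matrix: RatingMatrix | pd.DataFrame) -> CorrelationStructure:
    """Pearson correlations between scales across stimuli/instances."""
    df = _as_frame(matrix)
    if len(df) < 3:
        raise ValueError("need at least 3 rows to correlate scales")
    sd = df.to_numpy(float).std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(df.columns, sd) if s == 0]
        raise ValueError(f"constant scale column(s): {bad}")
    corr = pd.DataFrame(
        np.corrcoef(df.to_numpy(float), rowvar=False),
        index=df.columns,
        columns=df.columns,
    )
    return CorrelationStructure(corr)


def seriate(structure: CorrelationStructure, method: str = "average") -> list:
    """Display ordering: dendrogram leaf order on distance 1 - r.

    The ordering groups correlated scales into contiguous blocks for
    heatmap display; it is also stored on the structure.
    """
    c = structure.corr.to_numpy().copy()
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method=method)
    leaves = hierarchy.leaves_list(
        hierarchy.optimal_leaf_ordering(link, squareform(d, checks=False))
    )
    order = [structure.scales[i] for i in leaves]
    structure.order = order
    return order


def _fisher_z(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1.0 - 1e-12).any():
        warnings.warn("|r| = 1 entries clamped before the z-transform")
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)).clip(-_Z_CLAMP, _Z_CLAMP)


def second_order(
    c1: CorrelationStructure,
    c2: CorrelationStructure,
    shared_scales=None,
) -> SecondOrderResult:
    """Spearman rho between the Fisher-z lower triangles of two
    structures, restricted to a shared scale roster (same order)."""
    if shared_scales is None:
        shared_scales = [s for s in c1.scales if s in set(c2.scales)]
    a = c1.restrict(shared_scales).lower_triangle()
    b = c2.restrict(shared_scales).lower_triangle()
    rho = stats.spearmanr(_fisher_z(a), _fisher_z(b)).statistic
    return SecondOrderResult(rho=float(rho))


def perm_test(
    c1: CorrelationStructure,
    c2: CorrelationStructure,
    shared_scales=None,
    n: int = 10_000,
    seed: int = 0,
) -> SecondOrderResult:
    """Permutation test of second-order similarity.

    Rows and columns of the second matrix are permuted jointly (the
    same permutation for both, preserving symmetry); the one-sided
    empirical p uses the add-one rule p = (1 + #{rho_perm >= rho_obs})
    / (n + 1), so p is never exactly 0.
    """
    if n < 100:
        warnings.warn(f"only {n} permutations; p-value resolution is coarse")
    if shared_scales is None:
        shared_scales = [s for s in c1.scales if s in set(c2.scales)]
    shared_scales = list(shared_scales)
    a = _fisher_z(c1.restrict(shared_scales).lower_triangle())
    b_mat = c2.restrict(shared_scales).corr.to_numpy()
    p_scales = len(shared_scales)
    il, jl = np.tril_indices(p_scales, k=-1)

    rank_a = stats.rankdata(a)
    ra = rank_a - rank_a.mean()
    rng = np.random.default_rng(seed)

    def spearman_with(bmat2d):
        rb = stats.rankdata(bmat2d, axis=1)
        rb = rb - rb.mean(axis=1, keepdims=True)
        num = rb @ ra
        den = np.sqrt((rb**2).sum(axis=1) * (ra**2).sum())
        return num / den

    rho_obs = float(spearman_with(_fisher_z(b_mat[il, jl])[None, :])[0])
    n = int(n)
    count = 0
    # permutations in blocks to bound memory
    for start in range(0, n, 2000):
        block = min(2000, n - start)
        perms = np.array([rng.permutation(p_scales) for _ in range(block)])
        bp = b_mat[perms[:, :, None], perms[:, None, :]]  # (block, p, p)
        vecs = _fisher_z(bp[:, il, jl])
        count += int((spearman_with(vecs) >= rho_obs).sum())
    p = (1.0 + count) / (n + 1.0)
    return SecondOrderResult(rho=rho_obs, p=p, n_perm=int(n), seed=seed)
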