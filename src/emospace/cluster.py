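"""Cluster structure of emotion instances.

Hierarchical agglomerative clustering with Euclidean distance and
Ward linkage on the raw 1-7 ratings (deliberately unstandardized: the
per-scale variances are informative), K-means recovery of intended
categories scored by chance-corrected agreement (ARI/AMI), a dip test
of unimodality on the pairwise-distance distribution, and selection of
prototypical basic-emotion instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, adjusted_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from ._dip import dip_test
from .factor import _as_frame

__all__ = [
    "ClusteringResult",
    "DipResult",
    "hac",
    "kmeans_agreement",
    "dip_unimodality",
    "select_basic_instances",
    "BASIC_EMOTIONS",
]

log = logging.getLogger(__name__)

#: the six classical basic-emotion categories
BASIC_EMOTIONS = ("happiness", "surprise", "fear", "anger", "disgust", "sadness")


@dataclass
class ClusteringResult:
    """Linkage tree and/or flat labels plus agreement metrics."""

    labels: np.ndarray
    linkage: np.ndarray | None = None
    cuts: dict = field(default_factory=dict)       # n_clusters -> labels
    inertia: float | None = None
    seed: int | None = None
    ari: float | None = None
    ami: float | None = None
    contingency: pd.DataFrame | None = None


@dataclass
class DipResult:
    statistic: float
    p: float
    n_distances: int


def hac(matrix, cuts=(2, 4)) -> ClusteringResult:
    """Ward/Euclidean hierarchical clustering of the rating matrix.

    Returns the full linkage and flat labels at the requested cuts
    (default 2 and 4, the valence and valence-by-arousal partitions).
    """
    x = _as_frame(matrix).to_numpy(float)
    if len(x) < 2:
        raise ValueError("need at least 2 rows to cluster")
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    cut_labels = {
        k: hierarchy.fcluster(link, t=k, criterion="maxclust") for k in cuts
    }
    first = cut_labels[cuts[0]] if cuts else np.zeros(len(x), dtype=int)
    return ClusteringResult(labels=first, linkage=link, cuts=cut_labels)


def kmeans_agreement(
    matrix, reference, k: int | None = None, seed: int = 0, n_init: int = 10
) -> ClusteringResult:
    """K-means recovery of reference categories.

    ``k`` defaults to the number of reference categories.  Agreement is
    scored by the adjusted Rand index and adjusted mutual information;
    the contingency table (reference x predicted) is attached.
    """
    x = _as_frame(matrix).to_numpy(float)
    reference = np.asarray(reference)
    if len(reference) != len(x):
        raise ValueError("reference labels do not match row count")
    if k is None:
        k = len(np.unique(reference))
    if k > len(x):
        raise ValueError("more clusters than rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    cont = contingency_matrix(reference, km.labels_)
    return ClusteringResult(
        labels=km.labels_,
        inertia=float(km.inertia_),
        seed=seed,
        ari=float(adjusted_rand_score(reference, km.labels_)),
        ami=float(adjusted_mutual_info_score(reference, km.labels_)),
        contingency=pd.DataFrame(
            cont,
            index=np.unique(reference),
            columns=[f"k{j}" for j in range(cont.shape[1])],
        ),
    )


def dip_unimodality(matrix, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Hartigan dip test on the pairwise Euclidean distances.

    Tests whether the distribution of all pairwise distances between
    instances in the original high-dimensional rating space deviates
    from unimodality (a small p rejects the single-cloud picture).
    """
    x = _as_frame(matrix).to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 rows")
    d = pdist(x)
    if np.all(d == 0):
        raise ValueError("all rows identical: distance distribution degenerate")
    stat, p = dip_test(d, n_boot=n_boot, seed=seed)
    return DipResult(statistic=stat, p=p, n_distances=len(d))


def select_basic_instances(
    matrix6, per_category: int = 5, threshold: float = 6.0
) -> dict:
    """Prototypical instances of the six basic emotions.

    ``matrix6`` must have exactly the six basic-emotion scales as
    columns.  Per category: candidates need a rating strictly above
    ``threshold`` on that scale; candidates are ranked by Euclidean
    distance to the perfect prototype (7 on the category scale, 1
    elsewhere; ties broken by instance id) and the closest
    ``per_category`` are returned.  Categories without candidates map
    to an empty list.
    """
    df = _as_frame(matrix6)
    if df.shape[1] != 6:
        raise ValueError("expected exactly the six basic-emotion scales")
    out = {}
    for scale in df.columns:
        perfect = pd.Series(1.0, index=df.columns)
        perfect[scale] = 7.0
        cand = df[df[scale] > threshold]
        if cand.empty:
            log.info("no candidates above %.1f for %s", threshold, scale)
            out[scale] = []
            continue
        dist = np.sqrt(((cand - perfect) ** 2).sum(axis=1))
        ranked = dist.to_frame("dist").assign(id=dist.index.astype(str))
        ranked = ranked.sort_values(["dist", "id"])
        out[scale] = list(ranked.index[:per_category])
    return out
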