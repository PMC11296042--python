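"""Linear autoencoder with a k-unit bottleneck.

A single-hidden-layer autoencoder with linear activations and squared
loss: the optimal encoder/decoder span the top-k principal subspace of
the (centered) training data, so the model is fitted exactly by SVD
rather than gradient descent.  Cross-validation trains on the
aggregate ratings of one random half of the raters and scores the
reconstruction of the other half's aggregates, for bottleneck widths
k = 1..8; the decoder weights are comparable to EFA loadings via
Tucker congruence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RatingTable

__all__ = ["LinearAutoencoder", "AutoencoderCV", "linear_autoencoder_cv"]


class LinearAutoencoder:
    """Least-squares linear autoencoder (exact SVD solution)."""

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("bottleneck width must be >= 1")
        self.k = int(k)
        self.mean_: np.ndarray | None = None
        self.decoder_: np.ndarray | None = None  # (p, k) orthonormal columns

    def fit(self, x) -> "LinearAutoencoder":
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        _, _, vt = np.linalg.svd(x - self.mean_, full_matrices=False)
        self.decoder_ = vt[: self.k].T
        return self

    def encode(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean_) @ self.decoder_

    def reconstruct(self, x) -> np.ndarray:
        return self.encode(x) @ self.decoder_.T + self.mean_

    def reconstruction_error(self, x) -> float:
        """Mean squared reconstruction error per cell."""
        x = np.asarray(x, dtype=float)
        return float(((x - self.reconstruct(x)) ** 2).mean())


@dataclass
class AutoencoderCV:
    test_error: pd.DataFrame       # iterations x k
    train_error: pd.DataFrame      # iterations x k
    decoder_weights: dict = field(default_factory=dict)  # k -> (p, k) array
    scale_ids: list = field(default_factory=list)

    @property
    def mean_curves(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"train": self.train_error.mean(), "test": self.test_error.mean()}
        )


def _half_aggregates(df: pd.DataFrame, rng: np.random.Generator):
    """Split raters (sessions) per scale and aggregate each half."""
    acols, bcols = {}, {}
    for scale, grp in df.groupby("scale_id"):
        wide = grp.pivot_table(
            index="stimulus_id", columns="session_id", values="rating"
        )
        cols = rng.permutation(wide.shape[1])
        half = wide.shape[1] // 2
        acols[scale] = wide.iloc[:, cols[:half]].mean(axis=1)
        bcols[scale] = wide.iloc[:, cols[half:]].mean(axis=1)
    return pd.DataFrame(acols), pd.DataFrame(bcols)


def linear_autoencoder_cv(
    table: RatingTable,
    k_range=range(1, 9),
    n_iter: int = 10,
    seed: int = 0,
) -> AutoencoderCV:
    """Half-rater cross-validated bottleneck-width curves.

    Per iteration the raters of each scale are split at random; the
    autoencoder is trained on half A's stimulus-by-scale aggregate and
    scored on half B's.  Decoder weights at each k, fitted on the full
    aggregate, are stored for congruence with factor loadings.
    """
    df = table.main_trials()
    k_range = list(k_range)
    rng = np.random.default_rng(seed)
    train = np.full((n_iter, len(k_range)), np.nan)
    test = np.full((n_iter, len(k_range)), np.nan)
    for it in range(n_iter):
        a, b = _half_aggregates(df, rng)
        b = b[a.columns]
        for kk, k in enumerate(k_range):
            ae = LinearAutoencoder(k).fit(a.to_numpy())
            train[it, kk] = ae.reconstruction_error(a.to_numpy())
            test[it, kk] = ae.reconstruction_error(b.to_numpy())
    full = df.pivot_table(index="stimulus_id", columns="scale_id", values="rating")
    weights = {
        k: LinearAutoencoder(k).fit(full.to_numpy()).decoder_ for k in k_range
    }
    return AutoencoderCV(
        test_error=pd.DataFrame(test, columns=k_range),
        train_error=pd.DataFrame(train, columns=k_range),
        decoder_weights=weights,
        scale_ids=list(full.columns),
    )
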