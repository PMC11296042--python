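"""Factor-analytic models of the stimulus-by-scale rating matrix.

statsmodels-style objects: :class:`ExploratoryFactorAnalysis` and
:class:`PrincipalComponents` are built from a rating matrix (or plain
DataFrame/array); ``fit(k)`` returns a :class:`FactorResults` carrying
the pattern loadings, factor correlations, uniquenesses, factor scores,
per-factor shares of common variance, and a ``summary()`` table.

Extraction is minimum-residual (minres): the uniquenesses are chosen to
minimize the sum of squared off-diagonal residuals of the correlation
matrix, with the rank-k common part obtained by eigen-truncation.
Solutions are rotated with oblimin (direct quartimin, gamma = 0) for
EFA and varimax for PCA; oblique factor scores use the Ten Berge
correlation-preserving estimator.  Factor similarity is measured by
Tucker's congruence coefficient after orthogonal Procrustes alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from statsmodels.multivariate.factor_rotation import rotate_factors

from .data import RatingMatrix

__all__ = [
    "ExploratoryFactorAnalysis",
    "PrincipalComponents",
    "FactorResults",
    "CongruenceResult",
    "tucker_congruence",
    "minres_extract",
    "ml_extract",
]


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, RatingMatrix):
        return data.values
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (initial communality estimates)."""
    try:
        rinv = np.linalg.inv(corr)
        return np.clip(1.0 - 1.0 / np.diag(rinv), 0.0, 1.0)
    except np.linalg.LinAlgError:
        return np.full(corr.shape[0], 0.5)


def _truncated_loadings(reduced: np.ndarray, k: int) -> np.ndarray:
    """Rank-k loading factorization of a reduced correlation matrix."""
    vals, vecs = np.linalg.eigh(reduced)
    order = np.argsort(vals)[::-1][:k]
    d = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(d)


def minres_extract(corr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-residual factor extraction.

    Returns (unrotated loadings (p, k), uniquenesses (p,)).  The
    uniquenesses minimize the off-diagonal residual sum of squares; a
    Heywood solution (communality > 1) is capped with a warning.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]

    # Concentrated objective: with Lambda the rank-k eigen-truncation of
    # R - diag(psi), the residual sum of squares equals the sum of the
    # squared discarded eigenvalues; its gradient in psi_i is
    # -2 sum_{j>k} lambda_j v_ji^2 (psi absorbs the diagonal slack).
    def objective(psi):
        vals, vecs = np.linalg.eigh(corr - np.diag(psi))
        order = np.argsort(vals)[::-1]
        tail_vals = vals[order[k:]]
        tail_vecs = vecs[:, order[k:]]
        f = float((tail_vals**2).sum())
        grad = -2.0 * (tail_vecs**2) @ tail_vals
        return f, grad

    psi0 = np.clip(1.0 - _smc(corr), 0.005, 0.995)
    res = optimize.minimize(
        objective,
        psi0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p,
        options={"maxiter": 1000},
    )
    psi = res.x
    lam = _truncated_loadings(corr - np.diag(psi), k)
    comm = (lam**2).sum(axis=1)
    if (comm > 1.0 + 1e-8).any():
        warnings.warn("Heywood case: communality > 1 capped at 1")
        lam *= np.minimum(1.0, 1.0 / np.sqrt(comm))[:, None]
    psi = np.clip(1.0 - (lam**2).sum(axis=1), 0.0, 1.0)
    return lam, psi


def ml_extract(corr: np.ndarray, k: int, n_obs: int):
    """Maximum-likelihood factor extraction (profile over uniquenesses).

    Returns (loadings, uniquenesses, chi2, df) with Bartlett-corrected
    chi-square of the k-factor model.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]

    def profile_obj(logpsi):
        psi = np.exp(logpsi)
        d = 1.0 / np.sqrt(psi)
        rstar = corr * np.outer(d, d)
        theta = np.sort(np.linalg.eigvalsh(rstar))[::-1]
        tail = np.clip(theta[k:], 1e-12, None)
        return float(np.sum(tail - np.log(tail) - 1.0))

    logpsi0 = np.log(np.clip(1.0 - _smc(corr), 0.02, 0.95))
    res = optimize.minimize(
        profile_obj, logpsi0, method="L-BFGS-B",
        bounds=[(np.log(1e-3), 0.0)] * p, options={"maxiter": 1000},
    )
    psi = np.exp(res.x)
    d = 1.0 / np.sqrt(psi)
    rstar = corr * np.outer(d, d)
    vals, vecs = np.linalg.eigh(rstar)
    order = np.argsort(vals)[::-1][:k]
    theta = vals[order]
    lam = (vecs[:, order] * np.sqrt(np.clip(theta - 1.0, 0.0, None))) / d[:, None]
    fmin = profile_obj(res.x)
    df = ((p - k) ** 2 - (p + k)) / 2.0
    correction = n_obs - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
    chi2 = max(correction, 0.0) * fmin
    return lam, psi, float(chi2), float(df)


def _tenberge_weights(
    corr: np.ndarray, pattern: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Ten Berge correlation-preserving factor-score weights.

    The resulting scores have correlation matrix exactly ``phi`` in the
    sample whose correlation matrix is ``corr``.
    """

    def msqrt(m, inv=False):
        vals, vecs = np.linalg.eigh(m)
        vals = np.clip(vals, 1e-12, None)
        d = 1.0 / np.sqrt(vals) if inv else np.sqrt(vals)
        return (vecs * d) @ vecs.T

    phi_sq = msqrt(phi)
    lam = pattern @ phi_sq  # structure-in-orthonormal-basis loadings
    r_inv_sq = msqrt(corr, inv=True)
    inner = lam.T @ np.linalg.solve(corr, lam)
    c = r_inv_sq @ lam @ msqrt(inner, inv=True)
    return r_inv_sq @ c @ phi_sq


@dataclass
class CongruenceResult:
    """Per-factor Tucker congruence after Procrustes alignment."""

    phi: np.ndarray          # per-column congruence
    rotation: np.ndarray | None  # alignment applied to the comparison matrix

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.phi))

    @property
    def min(self) -> float:
        return float(np.nanmin(self.phi))


def tucker_congruence(
    a: np.ndarray, b: np.ndarray, procrustes: bool = True
) -> CongruenceResult:
    """Column-wise Tucker congruence between two loading matrices.

    With ``procrustes`` (default) B is first aligned to A by the
    orthogonal Procrustes rotation (handles column sign flips,
    permutations, and rotational indeterminacy); then per column j,
    ``phi_j = sum_i A_ij B'_ij / sqrt(sum A_ij^2 * sum B'_ij^2)``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.ndim == 2 and a.shape[1] != b.shape[1] or a.shape[0] != b.shape[0]:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    rot = None
    if procrustes and a.shape[1] > 1:
        rot, _ = linalg.orthogonal_procrustes(b, a)
        b = b @ rot
    elif procrustes and a.shape[1] == 1:
        sign = np.sign(float(a[:, 0] @ b[:, 0])) or 1.0
        b = b * sign
        rot = np.array([[sign]])
    num = (a * b).sum(axis=0)
    den = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, np.nan)
    if np.isnan(phi).any():
        warnings.warn("zero-norm column: congruence undefined for that factor")
    return CongruenceResult(phi=phi, rotation=rot)


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------


class FactorResults:
    """Fitted factor/component solution.

    Attributes
    ----------
    loadings : DataFrame (scales x k), pattern matrix
    phi : ndarray (k, k), factor correlations (identity for PCA/varimax)
    uniqueness : Series, per-scale unique variance
    scores : DataFrame or None, per-stimulus factor/component scores
    var_proportions : Series, per-factor share of common variance
    method : str
    """

    def __init__(self, model, loadings, phi, uniqueness, scores, method):
        self.model = model
        cols = [f"F{j + 1}" for j in range(loadings.shape[1])]
        self.loadings = pd.DataFrame(loadings, index=model.scale_ids, columns=cols)
        self.phi = np.asarray(phi, dtype=float)
        self.uniqueness = pd.Series(uniqueness, index=model.scale_ids, name="psi")
        self.scores = scores
        self.method = method

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> pd.Series:
        lam = self.loadings.to_numpy()
        return pd.Series(
            np.sum((lam @ self.phi) * lam, axis=1),
            index=self.loadings.index,
            name="communality",
        )

    @property
    def structure(self) -> pd.DataFrame:
        """Structure loadings (correlations of scales with factors)."""
        return pd.DataFrame(
            self.loadings.to_numpy() @ self.phi,
            index=self.loadings.index,
            columns=self.loadings.columns,
        )

    @property
    def var_proportions(self) -> pd.Series:
        """Per-factor share of common variance (structure-loading SS,
        normalized to sum to 1 over retained factors)."""
        ss = (self.structure.to_numpy() ** 2).sum(axis=0)
        return pd.Series(ss / ss.sum(), index=self.loadings.columns, name="prop")

    @property
    def residual_corr(self) -> np.ndarray:
        """Off-diagonal residuals of the model-implied correlation."""
        lam = self.loadings.to_numpy()
        implied = lam @ self.phi @ lam.T
        resid = self.model.corr - implied
        np.fill_diagonal(resid, 0.0)
        return resid

    def congruence(self, other, procrustes: bool = True) -> CongruenceResult:
        """Tucker congruence of this solution's loadings with another
        results object's (or raw matrix's)."""
        b = other.loadings.to_numpy() if hasattr(other, "loadings") else other
        return tucker_congruence(self.loadings.to_numpy(), b, procrustes=procrustes)

    def summary(self) -> str:
        lines = [
            f"{self.method} solution, k={self.k}, n_obs={self.model.n_obs}",
            "",
            "Pattern loadings:",
            self.loadings.round(3).to_string(),
            "",
            "Factor correlations:",
            pd.DataFrame(
                self.phi, index=self.loadings.columns, columns=self.loadings.columns
            ).round(3).to_string(),
            "",
            "Share of common variance: "
            + ", ".join(
                f"{c}: {v:.1%}" for c, v in self.var_proportions.items()
            ),
            f"Mean communality: {self.communalities.mean():.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class _FactorModelBase:
    def __init__(self, data):
        self.data = _as_frame(data)
        self.scale_ids = list(self.data.columns)
        self.n_obs = len(self.data)
        x = self.data.to_numpy(dtype=float)
        if (x.std(axis=0) == 0).any():
            bad = [c for c, s in zip(self.scale_ids, x.std(axis=0)) if s == 0]
            raise ValueError(f"constant column(s): {bad}")
        self.corr = np.corrcoef(x, rowvar=False)
        self._z = (x - x.mean(axis=0)) / x.std(axis=0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        return cls(df)


class ExploratoryFactorAnalysis(_FactorModelBase):
    """EFA of a stimulus-by-scale matrix (minres + oblimin + Ten Berge).

    Operates on the Pearson correlation matrix of the columns; ratings
    are used untransformed.

    Examples
    --------
    >>> model = ExploratoryFactorAnalysis(matrix)   # doctest: +SKIP
    >>> res = model.fit(3)                          # doctest: +SKIP
    >>> res.var_proportions                         # doctest: +SKIP
    """

    def fit(
        self,
        n_factors: int,
        rotation: str = "oblimin",
        gamma: float = 0.0,
    ) -> FactorResults:
        k = int(n_factors)
        p = len(self.scale_ids)
        if not 1 <= k < p:
            raise ValueError(f"need 1 <= k < n_scales; got k={k}, p={p}")
        lam, psi = minres_extract(self.corr, k)
        phi = np.eye(k)
        if k > 1 and rotation == "oblimin":
            lam, t = rotate_factors(lam, "oblimin", gamma, "oblique")
            phi = t.T @ t
        elif k > 1 and rotation == "varimax":
            lam, _ = rotate_factors(lam, "varimax")
        elif rotation not in ("oblimin", "varimax", None, "none"):
            raise ValueError(f"unknown rotation {rotation!r}")
        # orient each factor so its largest loading is positive
        flip = np.sign(lam[np.abs(lam).argmax(axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        lam = lam * flip
        phi = phi * np.outer(flip, flip)
        weights = _tenberge_weights(self.corr, lam, phi)
        scores = pd.DataFrame(
            self._z @ weights,
            index=self.data.index,
            columns=[f"F{j + 1}" for j in range(k)],
        )
        return FactorResults(self, lam, phi, psi, scores, "EFA-minres-" + (rotation or "none"))


class PrincipalComponents(_FactorModelBase):
    """PCA of the correlation matrix with varimax-rotated components."""

    def fit(self, n_components: int, rotation: str = "varimax") -> FactorResults:
        k = int(n_components)
        p = len(self.scale_ids)
        if not 1 <= k <= p:
            raise ValueError(f"need 1 <= k <= n_scales; got k={k}")
        vals, vecs = np.linalg.eigh(self.corr)
        order = np.argsort(vals)[::-1][:k]
        lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
        if k > 1 and rotation == "varimax":
            lam, _ = rotate_factors(lam, "varimax")
        flip = np.sign(lam[np.abs(lam).argmax(axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        lam = lam * flip
        psi = np.clip(1.0 - (lam**2).sum(axis=1), 0.0, 1.0)
        # component scores via regression weights on the correlation matrix
        weights = np.linalg.solve(self.corr, lam)
        scores = pd.DataFrame(
            self._z @ weights,
            index=self.data.index,
            columns=[f"F{j + 1}" for j in range(k)],
        )
        return FactorResults(self, lam, np.eye(k), psi, scores, "PCA-" + (rotation or "none"))
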