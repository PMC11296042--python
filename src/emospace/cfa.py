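"""Confirmatory factor analysis by maximum likelihood.

Fits the covariance-structure model Sigma = Lambda Phi Lambda' + Psi on
a correlation matrix, with a fixed zero/free loading pattern, free
factor correlations (unit factor variances), and free uniquenesses, by
minimizing the Wishart ML discrepancy
F = log|Sigma| + tr(S Sigma^-1) - log|S| - p
with analytic gradients.  Chi-square = (N - 1) F; RMSEA =
sqrt(max(chi2 - df, 0) / (df (N - 1))).

Used by the retention cross-validation: the pattern comes from
thresholding an EFA solution on the other half of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["CFAResults", "ConfirmatoryFactorAnalysis", "rmsea"]


def rmsea(chi2: float, df: float, n_obs: int) -> float:
    """Root-mean-square error of approximation (floored at 0)."""
    if df <= 0 or n_obs <= 1:
        return float("nan")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n_obs - 1))))


@dataclass
class CFAResults:
    loadings: np.ndarray
    phi: np.ndarray
    uniqueness: np.ndarray
    fmin: float
    chi2: float
    df: float
    n_obs: int
    converged: bool

    @property
    def rmsea(self) -> float:
        return rmsea(self.chi2, self.df, self.n_obs)


class ConfirmatoryFactorAnalysis:
    """ML CFA with a fixed loading pattern.

    Parameters
    ----------
    corr : (p, p) sample correlation matrix
    pattern : (p, k) boolean mask of free loadings (True = estimated)
    n_obs : number of observations behind ``corr``
    """

    def __init__(self, corr: np.ndarray, pattern: np.ndarray, n_obs: int):
        self.s = np.asarray(corr, dtype=float)
        self.pattern = np.asarray(pattern, dtype=bool)
        self.n_obs = int(n_obs)
        self.p, self.k = self.pattern.shape
        if self.s.shape != (self.p, self.p):
            raise ValueError("corr shape does not match pattern")
        if (~self.pattern.any(axis=0)).any():
            raise ValueError("a factor has no free loadings")
        sign, self._logdet_s = np.linalg.slogdet(self.s)
        if sign <= 0:
            raise ValueError("sample correlation matrix is not positive definite")
        self.n_load = int(self.pattern.sum())
        self.n_phi = self.k * (self.k - 1) // 2
        self.n_free = self.n_load + self.n_phi + self.p
        self.df = self.p * (self.p + 1) / 2.0 - self.n_free

    # -- parameter packing -------------------------------------------
    def _unpack(self, theta):
        lam = np.zeros((self.p, self.k))
        lam[self.pattern] = theta[: self.n_load]
        w = theta[self.n_load : self.n_load + self.n_phi]
        psi = np.exp(theta[self.n_load + self.n_phi :])
        # unit-row-norm Cholesky factor -> Phi PD with unit diagonal
        t = np.eye(self.k)
        idx = 0
        norms = np.ones(self.k)
        for j in range(1, self.k):
            v = np.zeros(self.k)
            v[:j] = w[idx : idx + j]
            v[j] = 1.0
            idx += j
            norms[j] = np.linalg.norm(v)
            t[j] = v / norms[j]
        return lam, t, norms, psi

    def _value_grad(self, theta):
        lam, t, norms, psi = self._unpack(theta)
        phi = t @ t.T
        sigma = lam @ phi @ lam.T + np.diag(psi)
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        sigma_inv = np.linalg.inv(sigma)
        f = logdet + float((sigma_inv * self.s).sum()) - self._logdet_s - self.p
        # dF/dSigma
        g = sigma_inv @ (sigma - self.s) @ sigma_inv
        g_lam = 2.0 * g @ lam @ phi
        g_phi = lam.T @ g @ lam           # symmetric
        g_t = 2.0 * g_phi @ t
        g_psi = np.diag(g) * psi          # chain through log-psi
        # chain t rows through the normalization
        g_w = np.zeros(self.n_phi)
        idx = 0
        for j in range(1, self.k):
            proj = (g_t[j] - t[j] * float(t[j] @ g_t[j])) / norms[j]
            g_w[idx : idx + j] = proj[:j]
            idx += j
        grad = np.concatenate([g_lam[self.pattern], g_w, g_psi])
        return f, grad

    def fit(self, maxiter: int = 500) -> CFAResults:
        # start loadings at 0.5 on the free entries, Phi = I, psi = 0.5
        theta0 = np.concatenate(
            [
                np.full(self.n_load, 0.5),
                np.zeros(self.n_phi),
                np.full(self.p, np.log(0.5)),
            ]
        )
        res = optimize.minimize(
            self._value_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-10, 10)] * (self.n_load + self.n_phi)
            + [(np.log(1e-3), np.log(10.0))] * self.p,
            options={"maxiter": maxiter},
        )
        lam, t, _, psi = self._unpack(res.x)
        phi = t @ t.T
        chi2 = (self.n_obs - 1) * max(res.fun, 0.0)
        if not res.success:
            warnings.warn(f"CFA optimizer did not converge: {res.message}")
        return CFAResults(
            loadings=lam,
            phi=phi,
            uniqueness=psi,
            fmin=float(res.fun),
            chi2=float(chi2),
            df=self.df,
            n_obs=self.n_obs,
            converged=bool(res.success),
        )
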