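"""Principal preserved component analysis (PPCA).

PPCA finds directions of the scale space whose variation is *shared*
between two datasets of the same shape: it eigen-decomposes the
symmetrized cross-covariance (X'Y + Y'X) / 2 of two column-centered
matrices.  When Y = X it reduces exactly to PCA of X.  Significance of
components is assessed by a repeated-split leave-one-out procedure:
each stimulus's ratings are randomly halved into two sets, each
stimulus is held out in turn,
components are fitted on the remainder and the held-out rows of both
sets are projected; the held-out score vectors are correlated across
sets (partialling out all previous components), the whole split is
repeated, and each component's correlations are tested for a positive
median by a one-tailed Wilcoxon signed-rank test with Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import RatingTable
from .factor import _as_frame

__all__ = ["PPCA", "PPCAResults", "PPCACrossValidation", "ppca_loocv"]


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


@dataclass
class PPCAResults:
    """Eigen-structure of the symmetrized cross-covariance."""

    weights: np.ndarray       # (scales, m) eigenvectors, by descending eigenvalue
    eigenvalues: np.ndarray   # (m,) "preserved variances" (may be negative)
    scale_ids: list

    def project(self, x: np.ndarray) -> np.ndarray:
        """Component scores of (centered) data rows."""
        return np.asarray(x, dtype=float) @ self.weights

    def summary(self) -> str:
        lines = ["PPCA eigenvalues (preserved variance):"]
        for j, v in enumerate(self.eigenvalues):
            lines.append(f"  PPC{j + 1}: {v: .4f}")
        return "\n".join(lines)


class PPCA:
    """Model object for a pair of stimulus-by-scale matrices.

    ``PPCA(X, Y).fit(m)`` returns the leading m principal preserved
    components.  X and Y must have identical shape and column order;
    both are column-centered internally.
    """

    def __init__(self, x, y):
        xf, yf = _as_frame(x), _as_frame(y)
        if xf.shape != yf.shape:
            raise ValueError(f"shape mismatch: {xf.shape} vs {yf.shape}")
        if list(xf.columns) != list(yf.columns):
            raise ValueError("column rosters differ between the two datasets")
        self.scale_ids = list(xf.columns)
        self.x = _center(xf.to_numpy(float))
        self.y = _center(yf.to_numpy(float))

    def fit(self, m: int | None = None) -> PPCAResults:
        p = self.x.shape[1]
        m = p if m is None else int(m)
        if not 1 <= m <= p:
            raise ValueError(f"need 1 <= m <= {p}")
        n = self.x.shape[0]
        cross = (self.x.T @ self.y + self.y.T @ self.x) / (2.0 * (n - 1))
        vals, vecs = np.linalg.eigh(cross)
        order = np.argsort(vals)[::-1][:m]
        return PPCAResults(
            weights=vecs[:, order], eigenvalues=vals[order], scale_ids=self.scale_ids
        )


# ---------------------------------------------------------------------------
# Repeated-split LOOCV significance
# ---------------------------------------------------------------------------


def _partial_corr(a: np.ndarray, b: np.ndarray, confound: np.ndarray) -> float:
    """Pearson correlation of OLS residuals of a and b on ``confound``
    (with intercept); plain correlation when confound has no columns."""
    if confound.shape[1]:
        z = np.column_stack([np.ones(len(a)), confound])
        beta_a, *_ = np.linalg.lstsq(z, a, rcond=None)
        beta_b, *_ = np.linalg.lstsq(z, b, rcond=None)
        a = a - z @ beta_a
        b = b - z @ beta_b
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PPCACrossValidation:
    """Held-out cross-set component correlations and their tests."""

    correlations: pd.DataFrame  # reps x components, partialled held-out r
    p_values: np.ndarray        # per component, one-tailed Wilcoxon
    alpha: float
    bonferroni_alpha: float
    significant: np.ndarray     # per-component flags at the corrected level
    seed: int

    @property
    def n_significant(self) -> int:
        """Contiguous leading run of significant components."""
        flags = self.significant
        out = 0
        for f in flags:
            if not f:
                break
            out += 1
        return out

    @property
    def n_significant_total(self) -> int:
        return int(self.significant.sum())


def ppca_loocv(
    table: RatingTable,
    domain: str | None = None,
    n_rep: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
    m: int | None = None,
) -> PPCACrossValidation:
    """Repeated split-half + leave-one-out PPCA significance test.

    Per repetition: the ratings of every (stimulus, scale) cell are
    randomly halved — independently per stimulus, so one rater's trials
    scatter across both half-sets — and each half's means form one
    matrix; each stimulus is held out in turn, PPCA is fitted on the
    remaining stimuli, and the held-out rows of both sets are
    projected; the concatenated held-out
    score vectors are correlated across sets per component, partialling
    out all previous components by OLS.  Each component's ``n_rep``
    correlations are then tested for a positive median by a one-tailed
    Wilcoxon signed-rank test at the Bonferroni level alpha / m.
    """
    df = table.main_trials()
    if domain is not None:
        df = df[df["domain"] == domain]
    counts = df.groupby(["stimulus_id", "scale_id"]).size()
    if (counts < 2).any():
        raise ValueError("every (stimulus, scale) cell needs >= 2 ratings to split")
    scale_ids = sorted(df["scale_id"].unique())
    p = len(scale_ids)
    m = p if m is None else int(m)
    rng = np.random.default_rng(seed)

    # ratings per (stimulus, scale) cell as dense arrays; the split is
    # per cell, so one rater's trials scatter across both half-sets
    pivot = df.pivot_table(
        index="stimulus_id", columns=["scale_id", "session_id"], values="rating"
    )
    stim_ids = pivot.index
    n_stim = len(stim_ids)
    cells = {
        s: np.ma.masked_invalid(pivot[s].to_numpy(float)) for s in scale_ids
    }

    corrs = np.full((n_rep, m), np.nan)
    for rep in range(n_rep):
        xcols, ycols = [], []
        for s in scale_ids:
            arr = cells[s]  # (n_stim, n_raters) with missing masked
            n_raters = arr.shape[1]
            # independent per-stimulus random halving of the ratings
            order = np.argsort(rng.random((n_stim, n_raters)), axis=1)
            shuffled = np.take_along_axis(arr, order, axis=1)
            half = n_raters // 2
            xcols.append(shuffled[:, :half].mean(axis=1).filled(np.nan))
            ycols.append(shuffled[:, half:].mean(axis=1).filled(np.nan))
        x = _center(np.column_stack(xcols))
        y = _center(np.column_stack(ycols))
        sx = np.empty((n_stim, m))
        sy = np.empty((n_stim, m))
        mask = np.ones(n_stim, dtype=bool)
        for i in range(n_stim):
            mask[i] = False
            res = PPCA(x[mask], y[mask]).fit(m)
            mask[i] = True
            # deterministic sign convention (largest-|weight| element
            # positive): keeps signs consistent across leave-one-out fits
            # without reference to the held-out stimulus
            flip = np.sign(res.weights[np.abs(res.weights).argmax(axis=0),
                                       np.arange(m)])
            flip[flip == 0] = 1.0
            w = res.weights * flip
            sx[i] = x[i] @ w
            sy[i] = y[i] @ w
        for j in range(m):
            corrs[rep, j] = _partial_corr(sx[:, j], sy[:, j], sx[:, :j])

    bonf = alpha / m
    pvals = np.ones(m)
    for j in range(m):
        c = corrs[:, j]
        c = c[~np.isnan(c)]
        if len(c) == 0 or np.allclose(c, 0):
            continue
        pvals[j] = stats.wilcoxon(c, alternative="greater").pvalue
    return PPCACrossValidation(
        correlations=pd.DataFrame(
            corrs, columns=[f"PPC{j + 1}" for j in range(m)]
        ),
        p_values=pvals,
        alpha=alpha,
        bonferroni_alpha=bonf,
        significant=pvals < bonf,
        seed=seed,
    )
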