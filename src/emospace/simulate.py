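"""Synthetic rating data with known latent structure.

Every downstream stage of the pipeline (reliability, RSA, factor
retention and estimation, PPCA, embedding, clustering, individual
differences) is testable by recovery against the generator's ground
truth.  The generative model is a standard oblique common-factor model:
factor scores F ~ MVN(0, Phi), latent per-stimulus scale means
mu = c + g * (F Lambda' + e) with unique noise e ~ N(0, diag(Psi)),
mapped through a bounded 1-7 slider (clip).  Raters add a per-rater
bias and trial noise.  Optionally, factor scores are drawn around
planted category centroids (cluster recovery), and participant traits
are linked to rating means with planted effect sizes (individual
differences).

Defaults mimic the evoked-narrative study conditions: 150 stimuli x 23
scales, k = 3 oblique factors (pairwise correlation 0.2) interpretable
as valence / arousal / generalizability, ~20 raters per scale, 8 retest
trials per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import RatingTable, RatingMatrix, RATING_MIN, RATING_MAX

__all__ = [
    "RaterModel",
    "ClusterSpec",
    "TruthModel",
    "ParticipantSpec",
    "ParticipantTable",
    "default_truth",
    "generate_latent_dataset",
    "generate_rater_ratings",
    "generate_categorical_dataset",
    "generate_participants",
    "participant_scale_means",
]


@dataclass
class RaterModel:
    """Per-rater measurement model for trial-level data."""

    n_raters: int = 20
    bias_sd: float = 0.3      # stable per-rater offset, slider units
    noise_sd: float = 0.8     # trial noise, slider units
    n_retest: int = 8         # retest trials per session
    frac_fast_rt: float = 0.0       # planted fraction of invalid (<400 ms) trials
    frac_bad_attention: float = 0.0  # planted fraction of sessions with 2 fails


@dataclass
class ClusterSpec:
    """Planted category structure in factor space.

    Factor scores are drawn as ``separation * centroids[label] +
    within_sd * MVN(0, Phi)``; separation 0 recovers the unclustered
    generator exactly.
    """

    n_categories: int
    centroids: np.ndarray  # (n_categories, k)
    within_sd: float = 1.0
    separation: float = 1.0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.n_categories:
            raise ValueError(
                f"centroid count {self.centroids.shape[0]} != n_categories "
                f"{self.n_categories}"
            )
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


@dataclass
class TruthModel:
    """Ground-truth parameters of the synthetic rating generator."""

    loadings: np.ndarray          # (n_scales, k)
    phi: np.ndarray               # (k, k) factor correlations
    uniqueness: np.ndarray        # (n_scales,) unique variances
    n_stimuli: int = 150
    slider_center: float = 4.0
    gain: float = 1.0
    domain: str = "narrative"
    rater: RaterModel = field(default_factory=RaterModel)
    clusters: ClusterSpec | None = None
    scale_ids: list = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.uniqueness = np.asarray(self.uniqueness, dtype=float)
        p, k = self.loadings.shape
        if self.phi.shape != (k, k):
            raise ValueError("phi shape does not match loadings")
        if not np.allclose(self.phi, self.phi.T) or not np.allclose(
            np.diag(self.phi), 1.0
        ):
            raise ValueError("phi must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(self.phi).min() <= 0:
            raise ValueError("phi must be positive definite")
        if (self.uniqueness < 0).any():
            raise ValueError("unique variances must be >= 0")
        if (np.abs(self.loadings).sum(axis=0) == 0).any():
            raise ValueError("every factor must load on at least one scale")
        if self.scale_ids is None:
            self.scale_ids = [f"scale_{i:02d}" for i in range(p)]

    @property
    def n_scales(self) -> int:
        return self.loadings.shape[0]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def implied_cov(self) -> np.ndarray:
        """Population covariance of the latent scale values (pre-slider)."""
        return self.loadings @ self.phi @ self.loadings.T + np.diag(self.uniqueness)

    @property
    def implied_corr(self) -> np.ndarray:
        c = self.implied_cov
        d = 1.0 / np.sqrt(np.diag(c))
        return c * np.outer(d, d)


def default_truth(
    preset: str = "narrative",
    k: int = 3,
    seed: int = 0,
    noise_sd: float | None = None,
    **overrides,
) -> TruthModel:
    """Construct the default ground truth for a study preset.

    Presets: ``narrative`` (150 x 23), ``video`` (998 x 23),
    ``reallife`` (12861 x 18, single-rater).  The loading pattern is a
    bipolar simple structure: scales are assigned round-robin to the k
    factors with primary loadings alternating in sign between 0.6 and
    0.85, plus small (+-0.05..0.15) cross-loadings; factor correlations
    are 0.2 off-diagonal; unique variances complete each scale to unit
    latent variance.
    """
    presets = {
        "narrative": dict(n_stimuli=150, n_scales=23, domain="narrative"),
        "video": dict(n_stimuli=998, n_scales=23, domain="video"),
        "reallife": dict(n_stimuli=12861, n_scales=18, domain="real_life"),
    }
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}")
    cfg = presets[preset]
    p = cfg["n_scales"]
    rng = np.random.default_rng(seed)
    lam = np.zeros((p, k))
    for i in range(p):
        j = i % k
        sign = -1.0 if (i // k) % 2 else 1.0  # bipolar (valence-like) factors
        lam[i, j] = sign * rng.uniform(0.6, 0.85)
        cross = rng.choice([j2 for j2 in range(k) if j2 != j])
        lam[i, cross] = rng.uniform(-0.15, 0.15)
    phi = np.full((k, k), 0.2)
    np.fill_diagonal(phi, 1.0)
    common = np.diag(lam @ phi @ lam.T)
    psi = np.clip(1.0 - common, 0.05, None)
    rater = RaterModel() if preset != "reallife" else RaterModel(n_raters=1)
    tm = TruthModel(
        loadings=lam,
        phi=phi,
        uniqueness=psi,
        n_stimuli=cfg["n_stimuli"],
        domain=cfg["domain"],
        rater=rater,
        seed=seed,
    )
    if noise_sd is not None:
        tm.rater = replace(tm.rater, noise_sd=noise_sd)
    for key, val in overrides.items():
        setattr(tm, key, val)
    return tm


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _draw_factor_scores(truth: TruthModel, rng: np.random.Generator):
    """Factor scores (n_stimuli, k) plus category labels (or None)."""
    n, k = truth.n_stimuli, truth.k
    chol = np.linalg.cholesky(truth.phi)
    base = rng.standard_normal((n, k)) @ chol.T
    if truth.clusters is None:
        return base, None
    cs = truth.clusters
    labels = rng.integers(0, cs.n_categories, size=n)
    f = cs.separation * cs.centroids[labels] + cs.within_sd * base
    return f, labels


def _latent_means(truth: TruthModel, rng: np.random.Generator):
    """Per-(stimulus, scale) latent slider means, pre-clipping.

    Returns (means, factor_scores, labels).
    """
    f, labels = _draw_factor_scores(truth, rng)
    e = rng.standard_normal((truth.n_stimuli, truth.n_scales)) * np.sqrt(
        truth.uniqueness
    )
    mu = truth.slider_center + truth.gain * (f @ truth.loadings.T + e)
    return mu, f, labels


def generate_latent_dataset(
    truth: TruthModel, seed: int | None = None
) -> tuple[RatingMatrix, TruthModel]:
    """Draw one stimulus-by-scale aggregate matrix from the truth model.

    Slider values are clipped to [1, 7]; with the default gain the
    clipped mass is ~1%, so sample covariances track the model-implied
    ``gain^2 * Lambda Phi Lambda' + Psi`` closely.  The truth is
    returned unchanged for recovery tests.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    mu, f, labels = _latent_means(truth, rng)
    vals = np.clip(mu, RATING_MIN, RATING_MAX)
    idx = [f"stim_{i:05d}" for i in range(truth.n_stimuli)]
    df = pd.DataFrame(vals, index=idx, columns=truth.scale_ids)
    df.index.name = "stimulus_id"
    row_labels = None
    if labels is not None:
        row_labels = pd.Series(labels, index=df.index, name="category")
    mat = RatingMatrix(
        df,
        domain=truth.domain,
        aggregation="rater-mean" if truth.domain != "real_life" else "single-rater",
        row_labels=row_labels,
    )
    mat.factor_scores = pd.DataFrame(
        f, index=df.index, columns=[f"F{j + 1}" for j in range(truth.k)]
    )
    return mat, truth


def generate_categorical_dataset(
    truth: TruthModel, seed: int | None = None
) -> tuple[RatingMatrix, TruthModel]:
    """Aggregate matrix with planted category labels attached."""
    if truth.clusters is None:
        raise ValueError("truth model carries no cluster spec")
    return generate_latent_dataset(truth, seed=seed)


def generate_rater_ratings(truth: TruthModel, seed: int | None = None) -> RatingTable:
    """Trial-level ratings: one session per (rater, scale).

    Each of ``rater.n_raters`` raters per scale rates every stimulus
    once (main trials) plus ``rater.n_retest`` randomly chosen stimuli
    again with fresh trial noise (retest trials).  Ratings are
    ``clip(latent mean + rater bias + noise, 1, 7)``.  Reaction times
    are log-normal (median ~2 s); a ``frac_fast_rt`` fraction of trials
    is planted with RT < 400 ms and a ``frac_bad_attention`` fraction of
    sessions with 2 failed attention checks, for exclusion testing.
    """
    rm = truth.rater
    if rm.n_retest > truth.n_stimuli:
        raise ValueError("retest count exceeds number of stimuli")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    mu, _, _ = _latent_means(truth, rng)
    n, p = mu.shape
    stim_ids = np.array([f"stim_{i:05d}" for i in range(n)])

    cols = {c: [] for c in (
        "participant_id", "session_id", "domain", "stimulus_id", "scale_id",
        "rating", "trial_type", "reaction_time_ms", "attention_fails",
    )}

    def emit(stims_idx, scale, j, sess, part, bias, fails, trial_type):
        m = len(stims_idx)
        ratings = np.clip(
            mu[stims_idx, j] + bias + rng.standard_normal(m) * rm.noise_sd,
            RATING_MIN,
            RATING_MAX,
        )
        rt = np.exp(rng.normal(np.log(2000.0), 0.4, size=m))
        fast = rng.random(m) < rm.frac_fast_rt
        rt[fast] = rng.uniform(100.0, 399.0, size=int(fast.sum()))
        cols["participant_id"].append(np.repeat(part, m))
        cols["session_id"].append(np.repeat(sess, m))
        cols["domain"].append(np.repeat(truth.domain, m))
        cols["stimulus_id"].append(stim_ids[stims_idx])
        cols["scale_id"].append(np.repeat(scale, m))
        cols["rating"].append(ratings)
        cols["trial_type"].append(np.repeat(trial_type, m))
        cols["reaction_time_ms"].append(rt)
        cols["attention_fails"].append(np.repeat(fails, m))

    for j, scale in enumerate(truth.scale_ids):
        biases = rng.standard_normal(rm.n_raters) * rm.bias_sd
        for r in range(rm.n_raters):
            sess = f"sess_{scale}_{r:03d}"
            part = f"part_{scale}_{r:03d}"
            fails = 2 if rng.random() < rm.frac_bad_attention else 0
            emit(np.arange(n), scale, j, sess, part, biases[r], fails, "main")
            retest_idx = rng.choice(n, size=rm.n_retest, replace=False)
            emit(retest_idx, scale, j, sess, part, biases[r], fails, "retest")

    df = pd.DataFrame({c: np.concatenate(v) for c, v in cols.items()})
    df["reaction_time_ms"] = df["reaction_time_ms"].astype(float)
    df["rating"] = df["rating"].astype(float)
    df["attention_fails"] = df["attention_fails"].astype(int)
    return RatingTable(df, validate=False)


# ---------------------------------------------------------------------------
# Participants / individual differences
# ---------------------------------------------------------------------------


@dataclass
class ParticipantSpec:
    """Planted trait-rating structure for the association screen.

    ``trait_effects[(trait, scale)] = r`` plants a Pearson correlation r
    between the standardized trait and the participant's mean rating on
    that scale; ``group_effects[(group, scale)] = d`` plants a Cohen's-d
    mean shift (group 1 minus group 0).  Unlisted pairs are null.
    """

    n_participants: int = 441
    traits: tuple = ("extraversion", "neuroticism", "openness", "anxiety")
    groups: tuple = ("sex", "education", "party")
    scales: tuple = tuple(f"scale_{i:02d}" for i in range(18))
    trait_effects: dict = field(default_factory=dict)
    group_effects: dict = field(default_factory=dict)


@dataclass
class ParticipantTable:
    """Traits/groups per participant plus the planted effect sizes."""

    traits: pd.DataFrame   # participants x continuous traits (standardized)
    groups: pd.DataFrame   # participants x binary group labels (0/1)
    spec: ParticipantSpec


def generate_participants(spec: ParticipantSpec, seed: int = 0) -> ParticipantTable:
    """Draw participant traits (standard normal) and balanced binary groups."""
    rng = np.random.default_rng(seed)
    idx = pd.Index(
        [f"part_{i:04d}" for i in range(spec.n_participants)], name="participant_id"
    )
    traits = pd.DataFrame(
        rng.standard_normal((spec.n_participants, len(spec.traits))),
        index=idx,
        columns=list(spec.traits),
    )
    groups = pd.DataFrame(
        rng.integers(0, 2, size=(spec.n_participants, len(spec.groups))),
        index=idx,
        columns=list(spec.groups),
    )
    return ParticipantTable(traits=traits, groups=groups, spec=spec)


def participant_scale_means(
    table: ParticipantTable, seed: int = 0
) -> pd.DataFrame:
    """Participant-by-scale mean ratings with the planted associations.

    Each scale's mean vector is built as the planted linear combination
    of traits and group contrasts plus independent residual noise scaled
    so the marginal variance is 1 (hence trait effect sizes are
    population Pearson correlations).
    """
    spec = table.spec
    rng = np.random.default_rng(seed)
    n = spec.n_participants
    out = {}
    for scale in spec.scales:
        signal = np.zeros(n)
        var = 0.0
        for trait in spec.traits:
            r = spec.trait_effects.get((trait, scale), 0.0)
            signal += r * table.traits[trait].to_numpy()
            var += r * r
        for group in spec.groups:
            d = spec.group_effects.get((group, scale), 0.0)
            g = table.groups[group].to_numpy()
            signal += d * (g - 0.5)
            var += d * d * 0.25
        if var >= 1.0:
            raise ValueError(f"planted effects on {scale!r} exceed unit variance")
        out[scale] = signal + rng.standard_normal(n) * np.sqrt(1.0 - var)
    return pd.DataFrame(out, index=table.traits.index)
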