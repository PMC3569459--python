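"""Presence-only maximum-entropy suitability models.

Each species gets a Gibbs distribution over the background pixels,
p(i) = exp(w.f_i) / Z, fitted by maximizing the L1-penalized presence
log-likelihood

    J(w) = (1/m) sum_presences w.f_i  -  log Z  -  beta * sum_j s_j |w_j|

where s_j is the feature's sample standard deviation over the presences
divided by sqrt(m) (the conventional per-feature penalty scale that makes a
single regularization multiplier beta meaningful across features). Features
are linear and quadratic terms of min-max-scaled predictors, which is enough
to express unimodal climatic niches. The optimizer is a monotone proximal
gradient ascent with backtracking, started at w = 0, so the fit is fully
deterministic.

Model quality is scored by replicated 70/30 presence splits evaluated with
the rank-based AUC of test presences against all background pixels, and
binary maps are cut at the threshold maximizing training sensitivity plus
specificity (background pixels serve as pseudo-absences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from ._seeds import rng_for
from .errors import DataError, EvaluationError, InputError, StateError
from .predictors import ClimateGrid

__all__ = [
    "FeatureSpec",
    "SuitabilityModel",
    "SuitabilityMap",
    "BinaryMap",
    "MaxentSuitability",
    "build_features",
    "fit_maxent",
    "predict",
    "auc",
    "evaluate_replicates",
    "threshold_max_ss",
    "binarize",
    "filter_species",
    "filter_by_auc",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Feature classes and per-variable min/max scaling over the background."""

    kinds: tuple = ("linear", "quadratic")
    scaling: Mapping | None = None  # var -> (min, max)

    def __post_init__(self):
        bad = set(self.kinds) - {"linear", "quadratic"}
        if bad or not self.kinds:
            raise InputError(f"feature kinds must be a nonempty subset of linear/quadratic, got {self.kinds}")
        if self.scaling is not None:
            for var, (lo, hi) in dict(self.scaling).items():
                if not hi > lo:
                    raise DataError(f"variable {var!r} has max <= min in feature scaling")


def build_features(grid: ClimateGrid, spec: FeatureSpec | None = None):
    """Pixel x feature matrix: min-max-scaled variables, linear block then
    quadratic block. Returns ``(matrix, feature_names, spec)`` with the
    scaling actually used (computed from the background when absent)."""
    if spec is None:
        spec = FeatureSpec()
    if spec.scaling is None:
        scaling = {}
        for j, var in enumerate(grid.variables):
            lo, hi = grid.values[:, j].min(), grid.values[:, j].max()
            if hi == lo:
                raise DataError(f"variable {var!r} is constant over the background")
            scaling[var] = (float(lo), float(hi))
        spec = FeatureSpec(spec.kinds, scaling)
    cols, names = [], []
    scaled = {}
    for j, var in enumerate(grid.variables):
        lo, hi = spec.scaling[var]
        scaled[var] = (grid.values[:, j] - lo) / (hi - lo)
    if "linear" in spec.kinds:
        for var in grid.variables:
            cols.append(scaled[var])
            names.append(f"{var}")
    if "quadratic" in spec.kinds:
        for var in grid.variables:
            cols.append(scaled[var] ** 2)
            names.append(f"{var}^2")
    return np.column_stack(cols), names, spec


def _soft_threshold(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


class MaxentSuitability(BaseEstimator):
    """Presence-only Gibbs suitability model with L1 regularization.

    Parameters
    ----------
    beta : regularization multiplier (default 2).
    max_iter : optimizer iteration cap (default 500).
    tol : stop when the penalized objective improves by less than this
        (default 1e-5).

    Attributes
    ----------
    coef_ : fitted feature weights.
    log_normalizer_ : log Z over the background used at fit time.
    objective_path_ : penalized objective after each accepted iteration
        (non-decreasing by construction).
    penalty_scale_ : per-feature penalty scales s_j.
    """

    def __init__(self, beta: float = 2.0, max_iter: int = 500, tol: float = 1e-5):
        self.beta = beta
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, sample_weight=None):
        """Fit on background features ``X`` with binary presence labels ``y``.

        ``sample_weight`` (applied to presence rows) expresses record
        multiplicity; background rows always enter the normalizer once.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise InputError("X must be 2-D with one label per background row")
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite feature values")
        pres_mask = y == 1
        if not pres_mask.any():
            raise InputError("no presence rows")
        weights = np.ones(X.shape[0]) if sample_weight is None else np.asarray(sample_weight, float)
        pw = weights[pres_mask]
        P = X[pres_mask]
        m = pw.sum()
        fbar = pw @ P / m
        # per-feature penalty scale: sample sd over presences / sqrt(m)
        var = pw @ (P - fbar) ** 2 / m
        if m > 1:
            var = var * m / (m - 1)
        scale = np.maximum(np.sqrt(var) / math.sqrt(m), 1e-6)
        lam = self.beta * scale

        def smooth(w):
            z = X @ w
            zmax = z.max()
            logZ = zmax + math.log(np.exp(z - zmax).sum())
            return fbar @ w - logZ, logZ

        def gradient(w):
            z = X @ w
            z -= z.max()
            p = np.exp(z)
            p /= p.sum()
            return fbar - p @ X

        w = np.zeros(X.shape[1])
        g_val, logZ = smooth(w)
        obj = g_val - lam @ np.abs(w)
        path = [obj]
        eta = 1.0
        for _ in range(self.max_iter):
            grad = gradient(w)
            while True:
                w_new = _soft_threshold(w + eta * grad, eta * lam)
                step = w_new - w
                g_new, logZ_new = smooth(w_new)
                if g_new >= g_val + grad @ step - (step @ step) / (2 * eta) - 1e-12:
                    break
                eta *= 0.5
                if eta < 1e-12:
                    w_new, g_new, logZ_new = w, g_val, logZ
                    break
            obj_new = g_new - lam @ np.abs(w_new)
            improvement = obj_new - obj
            w, g_val, logZ, obj = w_new, g_new, logZ_new, obj_new
            path.append(obj)
            eta *= 1.2
            if improvement < self.tol:
                break
        self.coef_ = w
        self.log_normalizer_ = logZ
        self.objective_path_ = np.array(path)
        self.penalty_scale_ = scale
        self.n_iter_ = len(path) - 1
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"feature dimension {X.shape[1]} does not match model ({self.n_features_in_})"
            )
        return X @ self.coef_

    def gibbs_probabilities(self, X):
        """Raw Gibbs p_i normalized over the given projection rows."""
        z = self.decision_function(X)
        z = z - z.max()
        p = np.exp(z)
        return p / p.sum()

    def predict_suitability(self, X):
        """Relative suitability in (0, 1]: raw Gibbs rescaled by its maximum."""
        z = self.decision_function(X)
        return np.exp(z - z.max())


@dataclass
class SuitabilityModel:
    """Fitted per-species model plus its evaluation/threshold state."""

    species: object
    weights: dict
    beta: float
    log_normalizer: float
    threshold: float | None = None
    auc_mean: float | None = None
    auc_replicates: list = field(default_factory=list)
    n_presences: int = 0
    estimator: MaxentSuitability | None = field(default=None, repr=False)


@dataclass
class SuitabilityMap:
    species: object
    values: Mapping  # pixel -> suitability in [0, 1]


@dataclass
class BinaryMap:
    species: object
    presence: Mapping  # pixel -> 0/1
    threshold: float


def fit_maxent(presences: Sequence[int], features: np.ndarray, beta: float = 2.0,
               max_iter: int = 500, tol: float = 1e-5,
               feature_names: Sequence[str] | None = None,
               species=None) -> SuitabilityModel:
    """Fit the Gibbs model for one species.

    ``presences`` are row indices into ``features`` (repeats express record
    multiplicity); the background is every row of ``features``.
    """
    presences = np.asarray(list(presences), dtype=int)
    if presences.size == 0:
        raise InputError("no presence pixels")
    features = np.asarray(features, dtype=float)
    if presences.min() < 0 or presences.max() >= features.shape[0]:
        raise InputError("presence indices outside the background")
    y = np.zeros(features.shape[0], dtype=int)
    weight = np.zeros(features.shape[0])
    for i in presences:
        y[i] = 1
        weight[i] += 1.0
    weight[weight == 0] = 1.0
    est = MaxentSuitability(beta=beta, max_iter=max_iter, tol=tol).fit(
        features, y, sample_weight=weight
    )
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(features.shape[1])
    ]
    return SuitabilityModel(
        species=species,
        weights=dict(zip(names, est.coef_.tolist())),
        beta=beta,
        log_normalizer=est.log_normalizer_,
        n_presences=int(len(set(presences.tolist()))),
        estimator=est,
    )


def predict(model: SuitabilityModel, features: np.ndarray,
            pixels: Sequence | None = None) -> SuitabilityMap:
    """Project the model: raw Gibbs probabilities rescaled by their maximum."""
    if model.estimator is None:
        raise StateError("model has no fitted estimator attached")
    values = model.estimator.predict_suitability(features)
    pixels = list(range(len(values))) if pixels is None else list(pixels)
    return SuitabilityMap(model.species, dict(zip(pixels, values.tolist())))


def auc(presence_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Rank-based AUC: probability a random presence outscores a random
    background point, ties counted 1/2."""
    pres = np.asarray(list(presence_scores), dtype=float)
    bg = np.asarray(list(background_scores), dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise InputError("AUC needs nonempty presence and background scores")
    labels = np.concatenate([np.ones(pres.size), np.zeros(bg.size)])
    scores = np.concatenate([pres, bg])
    if np.all(scores == scores[0]):
        return 0.5
    return float(roc_auc_score(labels, scores))


def evaluate_replicates(presences: Sequence[int], features: np.ndarray,
                        beta: float = 2.0, train_frac: float = 0.7,
                        n_reps: int = 10, seed: int = 0,
                        max_iter: int = 500, tol: float = 1e-5):
    """Replicated split evaluation: for each replicate a seeded random
    ``train_frac`` split of the presence pixels, a fit on the training part,
    and the AUC of test presences against all background pixels. Returns
    ``(auc_mean, auc_replicates)``."""
    presences = np.asarray(sorted(set(presences)), dtype=int)
    m = presences.size
    n_train = int(math.floor(train_frac * m))
    min_m = math.ceil(1.0 / (1.0 - train_frac))
    if m < min_m or n_train < 1 or m - n_train < 1:
        raise EvaluationError(f"too few presences ({m}) for a {train_frac:.0%} split")
    features = np.asarray(features, dtype=float)
    aucs = []
    for rep in range(n_reps):
        rng = rng_for(seed, "replicate", rep)
        perm = rng.permutation(m)
        train = presences[perm[:n_train]]
        test = presences[perm[n_train:]]
        model = fit_maxent(train, features, beta=beta, max_iter=max_iter, tol=tol)
        scores = model.estimator.predict_suitability(features)
        aucs.append(auc(scores[test], scores))
    return float(np.mean(aucs)), aucs


def threshold_max_ss(presence_suitability: Sequence[float],
                     background_suitability: Sequence[float]) -> float:
    """Threshold maximizing training sensitivity + specificity.

    Candidates are the unique observed suitability values; sensitivity is the
    fraction of presences >= t, specificity the fraction of background
    (pseudo-absence) pixels < t. Ties pick the smallest threshold.
    """
    pres = np.asarray(list(presence_suitability), dtype=float)
    bg = np.asarray(list(background_suitability), dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise InputError("threshold needs nonempty presence and background values")
    candidates = np.unique(np.concatenate([pres, bg]))
    sens = (pres[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (bg[None, :] < candidates[:, None]).mean(axis=1)
    total = sens + spec
    best = np.flatnonzero(total == total.max())[0]  # candidates sorted ascending
    return float(candidates[best])


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Cut a suitability map at a threshold (presence iff value >= t)."""
    presence = {p: int(v >= threshold) for p, v in smap.values.items()}
    return BinaryMap(smap.species, presence, threshold)


def filter_species(occurrences, min_occ: int = 10) -> list:
    """Species with strictly more than ``min_occ`` occupied pixels."""
    counts = occurrences.occupancy_counts()
    return sorted(counts.index[counts > min_occ].tolist())


def filter_by_auc(models: Sequence[SuitabilityModel], min_auc: float = 0.70) -> list:
    """Retain models whose replicate-mean AUC is at least ``min_auc``."""
    for model in models:
        if model.auc_mean is None:
            raise StateError(f"model for {model.species!r} has not been evaluated")
    return [m for m in models if m.auc_mean >= min_auc]
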