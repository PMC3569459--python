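"""Hellinger-distance k-means regionalization and cross-validated choice of k.

Pixels are clustered on their (potential) species composition. Rows are
Hellinger-transformed — y = sqrt(x / rowsum) — so the Euclidean distance
used by k-means equals the Hellinger distance between composition profiles
and shared absences carry no weight. Lloyd's algorithm is run from many
seeded random starts (initial centres drawn from distinct data rows) and the
restart with the lowest within-cluster sum of squared distances wins.

The number of regions is selected by v-fold cross-validation: for each k the
held-out cost (mean squared distance of held-out rows to the nearest trained
centre) is averaged over v folds, and k stops growing at the first k whose
relative improvement over k+1 falls below the error-disparity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from ._seeds import rng_for
from .assembly import AssemblageMatrix
from .errors import DataError, InputError

__all__ = [
    "RegionAssignment",
    "KSelectionReport",
    "HellingerTransformer",
    "MultiRestartKMeans",
    "VFoldKSelector",
    "hellinger_transform",
    "kmeans",
    "vfold_select_k",
]

logger = logging.getLogger(__name__)


def hellinger_transform(matrix) -> np.ndarray:
    """y[p, s] = sqrt(x[p, s] / rowsum_p); rows must have a positive sum."""
    x = matrix.values if isinstance(matrix, AssemblageMatrix) else np.asarray(matrix, float)
    rowsums = x.sum(axis=1, dtype=float)
    if np.any(rowsums <= 0):
        bad = np.flatnonzero(rowsums <= 0)
        raise DataError(f"rows with zero total abundance: indices {bad[:5].tolist()}")
    return np.sqrt(x / rowsums[:, None])


class HellingerTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying the Hellinger transform."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return hellinger_transform(X)


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int,
           unique_rows: np.ndarray | None = None):
    """One seeded Lloyd run. Returns (labels, centers, sse, sse_path).

    Initial centres are drawn from distinct data rows; when the data hold
    enough distinct *values*, those are preferred so duplicated rows do not
    spawn coinciding centres.
    """
    n = X.shape[0]
    if unique_rows is not None and len(unique_rows) >= k:
        centers = X[rng.choice(unique_rows, size=k, replace=False)].copy()
    else:
        centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    path = []
    for _ in range(max_iter):
        d = cdist(X, centers, "sqeuclidean")
        new_labels = d.argmin(axis=1)
        point_d = d[np.arange(n), new_labels]
        # re-seed empty clusters from the farthest point of a cluster that
        # can spare one (so the donor does not become empty in turn)
        counts = np.bincount(new_labels, minlength=k)
        for j in range(k):
            if counts[j] == 0:
                movable = counts[new_labels] > 1
                far = int(np.where(movable, point_d, -np.inf).argmax())
                counts[new_labels[far]] -= 1
                counts[j] += 1
                centers[j] = X[far]
                new_labels[far] = j
                point_d[far] = 0.0
        path.append(float(point_d.sum()))
        if np.array_equal(new_labels, labels) or path[-1] <= 1e-12:
            labels = new_labels
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
    d = cdist(X, centers, "sqeuclidean")
    labels = d.argmin(axis=1)
    sse = float(d[np.arange(n), labels].sum())
    path.append(sse)
    return labels, centers, sse, path


class MultiRestartKMeans(ClusterMixin, BaseEstimator):
    """Plain Lloyd k-means, best of ``n_restarts`` seeded random starts.

    Initial centres are sampled from distinct data rows (no k-means++), the
    within-restart SSE path is recorded, and cluster ids are relabelled to
    0..k-1 by first appearance so equal seeds give identical labellings.
    """

    def __init__(self, n_clusters: int = 2, n_restarts: int = 100,
                 max_iter: int = 300, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.n_clusters > n:
            raise InputError(f"k={self.n_clusters} exceeds {n} rows")
        _, first = np.unique(X, axis=0, return_index=True)
        best = None
        for r in range(self.n_restarts):
            rng = rng_for(self.random_state, "restart", r)
            labels, centers, sse, path = _lloyd(X, self.n_clusters, rng,
                                                self.max_iter, unique_rows=np.sort(first))
            if best is None or sse < best[2] - 1e-12:
                best = (labels, centers, sse, path)
        labels, centers, sse, path = best
        # relabel by first appearance
        remap, new = {}, 0
        out = np.empty_like(labels)
        for i, lab in enumerate(labels):
            if lab not in remap:
                remap[lab] = new
                new += 1
            out[i] = remap[lab]
        order = sorted(remap, key=remap.get)
        self.labels_ = out
        self.cluster_centers_ = centers[order]
        self.inertia_ = sse
        self.sse_path_ = path
        return self

    def predict(self, X):
        d = cdist(np.asarray(X, float), self.cluster_centers_, "sqeuclidean")
        return d.argmin(axis=1)


@dataclass
class RegionAssignment:
    """Pixel -> region labels (1..k) for one clustering run."""

    k: int
    labels: pd.Series
    sse: float
    restarts: int
    seed: int
    scheme: object = None

    def __post_init__(self):
        labs = np.asarray(self.labels)
        uniq = np.unique(labs)
        if not np.array_equal(uniq, np.arange(1, self.k + 1)):
            raise InputError(f"labels must be contiguous 1..{self.k}, got {uniq.tolist()}")
        if not np.isfinite(self.sse):
            raise InputError("sse must be finite")


def kmeans(data, k: int, n_restarts: int = 100, max_iter: int = 300,
           seed: int = 0, pixels: Sequence | None = None,
           scheme=None) -> RegionAssignment:
    """Best-of-restarts k-means on (Hellinger-transformed) rows."""
    X = np.asarray(data, dtype=float)
    est = MultiRestartKMeans(n_clusters=k, n_restarts=n_restarts,
                             max_iter=max_iter, random_state=seed).fit(X)
    pixels = list(range(X.shape[0])) if pixels is None else list(pixels)
    labels = pd.Series(est.labels_ + 1, index=pd.Index(pixels, name="pixel"), name="region")
    return RegionAssignment(k=k, labels=labels, sse=est.inertia_,
                            restarts=n_restarts, seed=seed, scheme=scheme)


@dataclass
class KSelectionReport:
    k_grid: list
    cv_error: dict  # k -> mean held-out cost
    disparity_threshold: float
    chosen_k: int
    v: int


class VFoldKSelector(BaseEstimator):
    """Choose k by v-fold cross-validated held-out clustering cost.

    For each fold, k-means (with a reduced restart budget) is fitted on the
    training rows and the held-out rows are charged the squared distance to
    their nearest trained centre. ``chosen_k_`` is the smallest k whose
    relative improvement over k+1, [cv(k) - cv(k+1)] / cv(k), falls below
    ``disparity``; if none does, the largest k of the grid (with a warning).
    """

    def __init__(self, k_grid: Sequence[int] = tuple(range(2, 26)), v: int = 50,
                 disparity: float = 0.03, n_restarts: int = 10,
                 max_iter: int = 100, random_state: int = 0):
        self.k_grid = k_grid
        self.v = v
        self.disparity = disparity
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k_grid = sorted(int(k) for k in self.k_grid)
        v = self.v
        if n < v:
            logger.warning("v=%d exceeds %d rows; lowering v to %d", v, n, n)
            v = n
        if np.all(np.all(X == X[0], axis=1)):
            logger.warning("all rows identical; choosing minimal k")
            self.cv_error_ = {k: 0.0 for k in k_grid}
            self.chosen_k_ = k_grid[0]
            self.report_ = KSelectionReport(k_grid, self.cv_error_, self.disparity,
                                            self.chosen_k_, v)
            return self
        rng = rng_for(self.random_state, "folds")
        folds = np.array_split(rng.permutation(n), v)
        cv_error: dict = {}
        for k in k_grid:
            costs = []
            for f, held in enumerate(folds):
                if len(held) == 0:
                    continue
                train = np.setdiff1d(np.arange(n), held)
                if len(train) < k:
                    continue
                est = MultiRestartKMeans(
                    n_clusters=k, n_restarts=self.n_restarts, max_iter=self.max_iter,
                    random_state=int(rng_for(self.random_state, "fold", k, f).integers(2**31)),
                ).fit(X[train])
                d = cdist(X[held], est.cluster_centers_, "sqeuclidean")
                costs.append(float(d.min(axis=1).mean()))
            cv_error[k] = float(np.mean(costs))
        chosen = None
        for k in k_grid[:-1]:
            nxt = k_grid[k_grid.index(k) + 1]
            if cv_error[k] <= 0:
                chosen = k
                break
            rel = (cv_error[k] - cv_error[nxt]) / cv_error[k]
            if rel < self.disparity:
                chosen = k
                break
        if chosen is None:
            logger.warning("no k reached the %.0f%% disparity threshold; "
                           "returning max of grid", 100 * self.disparity)
            chosen = k_grid[-1]
        self.cv_error_ = cv_error
        self.chosen_k_ = chosen
        self.report_ = KSelectionReport(k_grid, cv_error, self.disparity, chosen, v)
        return self


def vfold_select_k(data, k_grid: Sequence[int] = tuple(range(2, 26)), v: int = 50,
                   disparity: float = 0.03, seed: int = 0,
                   n_restarts: int = 10, max_iter: int = 100) -> KSelectionReport:
    """Functional wrapper over :class:`VFoldKSelector`."""
    sel = VFoldKSelector(k_grid=k_grid, v=v, disparity=disparity,
                         n_restarts=n_restarts, max_iter=max_iter,
                         random_state=seed).fit(np.asarray(data, float))
    return sel.report_
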