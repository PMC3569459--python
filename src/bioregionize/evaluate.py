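"""Scoring regionalizations.

Spatial coherence is measured with Moran's I on a binary lattice adjacency
(rook by default). For a categorical map the statistic is the size-weighted
mean of the per-region binary Moran's I values, with a Monte-Carlo
permutation p-value. Agreement with a reference region map uses the
confusion table: per-category overlap percentages, Cohen's kappa (global and
one-vs-rest per category) and the conventional verbal agreement labels.
Consistency between two regionalizations of the same pixels is the percent
of pixels matched under the optimal one-to-one cluster relabelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linear_sum_assignment

from ._seeds import rng_for
from .errors import DataError, InputError
from .regionalize import RegionAssignment

__all__ = [
    "AdjacencyWeights",
    "SpatialStats",
    "ConfusionTable",
    "AgreementReport",
    "build_adjacency",
    "morans_i_binary",
    "morans_i_categorical",
    "confusion",
    "overlap_percent",
    "cohen_kappa",
    "per_category_kappa",
    "agreement_label",
    "cross_scheme_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyWeights:
    """Symmetric binary spatial weights over an ordered pixel set."""

    pixels: list
    matrix: sparse.csr_matrix = field(repr=False)
    style: str = "rook"

    @property
    def total_weight(self) -> float:
        return float(self.matrix.sum())


def build_adjacency(coords: pd.DataFrame | Mapping, style: str = "rook") -> AdjacencyWeights:
    """Binary lattice adjacency among the given (retained) pixels.

    ``coords``: DataFrame indexed by pixel with integer row/col columns, or a
    mapping pixel -> (row, col). Rook joins |dr|+|dc| = 1; queen adds the
    diagonals.
    """
    if not isinstance(coords, pd.DataFrame):
        coords = pd.DataFrame(
            [(p, r, c) for p, (r, c) in dict(coords).items()],
            columns=["pixel", "row", "col"],
        ).set_index("pixel")
    pixels = list(coords.index)
    rc = list(zip(coords["row"].astype(int), coords["col"].astype(int)))
    if len(set(rc)) != len(rc):
        raise InputError("duplicate coordinates in grid")
    lookup = {pos: i for i, pos in enumerate(rc)}
    if style == "rook":
        offsets = [(0, 1), (1, 0)]
    elif style == "queen":
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    else:
        raise InputError(f"unknown adjacency style {style!r}")
    rows_idx, cols_idx = [], []
    for i, (r, c) in enumerate(rc):
        for dr, dc in offsets:
            j = lookup.get((r + dr, c + dc))
            if j is not None:
                rows_idx += [i, j]
                cols_idx += [j, i]
    n = len(pixels)
    w = sparse.csr_matrix(
        (np.ones(len(rows_idx)), (rows_idx, cols_idx)), shape=(n, n)
    )
    isolated = np.flatnonzero(np.asarray(w.sum(axis=1)).ravel() == 0)
    for i in isolated:
        logger.warning("pixel %r has no neighbours", pixels[i])
    return AdjacencyWeights(pixels, w, style)


@dataclass
class SpatialStats:
    morans_i: float
    p_value: float
    n_permutations: int


def _morans_i_vec(x: np.ndarray, w: sparse.csr_matrix, w_sum: float) -> float:
    n = x.size
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise DataError("Moran's I undefined for zero-variance values")
    return float(n / w_sum * (xc @ (w @ xc)) / denom)


def morans_i_binary(x, w: AdjacencyWeights) -> float:
    """Classic (non-row-standardized) Moran's I of one variable."""
    if isinstance(x, Mapping):
        x = np.array([x[p] for p in w.pixels], dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    if x.size != len(w.pixels):
        raise InputError("value vector does not match the weight pixel set")
    return _morans_i_vec(x, w.matrix, w.total_weight)


def _categorical_i(labels: np.ndarray, w: sparse.csr_matrix, w_sum: float) -> float:
    n = labels.size
    total = 0.0
    for region in np.unique(labels):
        ind = (labels == region).astype(float)
        total += ind.sum() / n * _morans_i_vec(ind, w, w_sum)
    return total


def morans_i_categorical(labels, w: AdjacencyWeights, n_permutations: int = 999,
                         seed: int = 0) -> SpatialStats:
    """Size-weighted mean of per-region binary Moran's I, with a seeded
    Monte-Carlo permutation p-value (labels shuffled over pixels)."""
    if isinstance(labels, RegionAssignment):
        labels = labels.labels
    if isinstance(labels, (pd.Series, Mapping)):
        mapping = dict(labels)
        labels = np.array([mapping[p] for p in w.pixels])
    else:
        labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DataError("Moran's I undefined with a single region")
    w_sum = w.total_weight
    observed = _categorical_i(labels, w.matrix, w_sum)
    rng = rng_for(seed, "moran")
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _categorical_i(perm, w.matrix, w_sum) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return SpatialStats(observed, p, n_permutations)


@dataclass
class ConfusionTable:
    """Square counts table on the union of test/reference categories."""

    counts: pd.DataFrame

    @property
    def N(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def categories(self) -> list:
        return list(self.counts.index)

    @classmethod
    def from_counts(cls, counts: Mapping | pd.DataFrame) -> "ConfusionTable":
        df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts).T
        df = df.fillna(0)
        cats = sorted(set(df.index) | set(df.columns), key=str)
        return cls(df.reindex(index=cats, columns=cats, fill_value=0).astype(int))


def confusion(labels, reference) -> ConfusionTable:
    """Cross-tabulate a test map against a reference map on shared pixels."""
    if isinstance(labels, RegionAssignment):
        labels = labels.labels
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    reference = (pd.Series(dict(reference))
                 if not isinstance(reference, pd.Series) else reference)
    common = labels.index.intersection(reference.index)
    if len(common) == 0:
        raise InputError("maps share no pixels")
    if len(common) < max(len(labels), len(reference)):
        logger.info("comparing %d shared pixels", len(common))
    tab = pd.crosstab(labels.loc[common], reference.loc[common])
    return ConfusionTable.from_counts(tab)


def overlap_percent(table: ConfusionTable, category) -> float:
    """100 x diagonal / row-total for one test-map category."""
    if category not in table.counts.index:
        raise InputError(f"category {category!r} not in table")
    row_total = table.counts.loc[category].sum()
    if row_total == 0:
        raise DataError(f"category {category!r} has an empty row")
    return 100.0 * table.counts.loc[category, category] / row_total


def cohen_kappa(table: ConfusionTable) -> float:
    """Chance-corrected agreement from the (square, zero-padded) table."""
    counts = table.counts.to_numpy(dtype=float)
    n = counts.sum()
    if n == 0:
        raise InputError("empty confusion table")
    p_o = np.trace(counts) / n
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / n**2
    if p_e >= 1.0:
        raise DataError("kappa undefined: expected agreement is 1 (single category)")
    return (p_o - p_e) / (1.0 - p_e)


def per_category_kappa(table: ConfusionTable, category) -> float:
    """One-vs-rest collapse to 2x2, then Cohen's kappa."""
    if category not in table.counts.index:
        raise InputError(f"category {category!r} not in table")
    counts = table.counts
    a = int(counts.loc[category, category])
    b = int(counts.loc[category].sum() - a)
    c = int(counts[category].sum() - a)
    d = int(table.N - a - b - c)
    collapsed = ConfusionTable(pd.DataFrame([[a, b], [c, d]],
                                            index=["cat", "rest"],
                                            columns=["cat", "rest"]))
    return cohen_kappa(collapsed)


_KAPPA_BANDS = [
    (0.85, "excellent"),
    (0.70, "very good"),
    (0.55, "good"),
    (0.40, "fair"),
    (0.20, "poor"),
]


def agreement_label(kappa: float) -> str:
    """Verbal agreement class for a kappa value (intervals closed on the left)."""
    if kappa > 1:
        raise InputError("kappa cannot exceed 1")
    for cut, label in _KAPPA_BANDS:
        if kappa >= cut:
            return label
    return "very poor"


def cross_scheme_overlap(a, b) -> float:
    """Percent of shared pixels assigned to matched regions under the optimal
    one-to-one cluster matching; symmetric, 100 iff identical up to
    relabelling."""
    a_labels = a.labels if isinstance(a, RegionAssignment) else pd.Series(dict(a))
    b_labels = b.labels if isinstance(b, RegionAssignment) else pd.Series(dict(b))
    common = a_labels.index.intersection(b_labels.index)
    if len(common) == 0:
        raise InputError("regionalizations share no pixels")
    tab = pd.crosstab(a_labels.loc[common], b_labels.loc[common]).to_numpy()
    rows, cols = linear_sum_assignment(-tab)
    matched = tab[rows, cols].sum()
    return 100.0 * matched / len(common)


@dataclass
class AgreementReport:
    global_kappa: float
    per_category_kappa: dict
    overlap_percent: dict
    labels: dict


def agreement_report(table: ConfusionTable) -> AgreementReport:
    """Global and per-category kappa, overlaps, and verbal labels for the
    test-map categories that actually contain pixels."""
    per_k, over, labels = {}, {}, {}
    for cat in table.categories:
        if table.counts.loc[cat].sum() == 0:
            continue
        per_k[cat] = per_category_kappa(table, cat)
        over[cat] = overlap_percent(table, cat)
        labels[cat] = agreement_label(per_k[cat])
    return AgreementReport(cohen_kappa(table), per_k, over, labels)
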