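"""Spatial coherence and map-agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from bioregionize.errors import DataError, InputError
from bioregionize.evaluate import (ConfusionTable, agreement_label,
                                   build_adjacency, cohen_kappa, confusion,
                                   cross_scheme_overlap, morans_i_binary,
                                   morans_i_categorical, overlap_percent,
                                   per_category_kappa)


def square_coords(n):
    pixels = range(n * n)
    return pd.DataFrame({"row": [p // n for p in pixels],
                         "col": [p % n for p in pixels]},
                        index=pd.Index(pixels, name="pixel"))


class TestAdjacency:
    def test_rook_edges_on_2x2(self):
        w = build_adjacency(square_coords(2), "rook")
        assert w.total_weight == 8  # 4 undirected edges

    def test_queen_edges_on_2x2(self):
        w = build_adjacency(square_coords(2), "queen")
        assert w.total_weight == 12  # 6 undirected edges

    def test_isolated_pixel_has_zero_row(self):
        coords = pd.DataFrame({"row": [0, 5], "col": [0, 5]},
                              index=pd.Index([0, 1], name="pixel"))
        w = build_adjacency(coords)
        assert w.matrix.sum() == 0

    def test_duplicate_coordinates_rejected(self):
        coords = pd.DataFrame({"row": [0, 0], "col": [0, 0]},
                              index=pd.Index([0, 1], name="pixel"))
        with pytest.raises(InputError):
            build_adjacency(coords)


def brute_force_moran(x, coords):
    """O(n^2) double-sum oracle with binary rook weights."""
    x = np.asarray(x, float)
    n = len(x)
    rc = list(zip(coords["row"], coords["col"]))
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and abs(rc[i][0] - rc[j][0]) + abs(rc[i][1] - rc[j][1]) == 1:
                w[i, j] = 1
    xc = x - x.mean()
    num = sum(w[i, j] * xc[i] * xc[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (xc @ xc)


class TestMoransBinary:
    def test_row_split_is_zero(self):
        w = build_adjacency(square_coords(2))
        assert morans_i_binary([1, 1, 0, 0], w) == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_is_minus_one(self):
        w = build_adjacency(square_coords(2))
        assert morans_i_binary([1, 0, 0, 1], w) == pytest.approx(-1.0)

    def test_line_matches_double_sum_oracle(self):
        coords = pd.DataFrame({"row": [0] * 4, "col": range(4)},
                              index=pd.Index(range(4), name="pixel"))
        w = build_adjacency(coords)
        x = [1, 1, 0, 0]
        assert morans_i_binary(x, w) == pytest.approx(brute_force_moran(x, coords),
                                                      abs=1e-12)

    def test_zero_variance_rejected(self):
        w = build_adjacency(square_coords(2))
        with pytest.raises(DataError):
            morans_i_binary([1, 1, 1, 1], w)


class TestMoransCategorical:
    def test_two_blocks_are_coherent(self):
        coords = square_coords(4)
        w = build_adjacency(coords)
        labels = pd.Series([1 if p // 4 < 2 else 2 for p in range(16)],
                           index=coords.index)
        stats = morans_i_categorical(labels, w, n_permutations=999, seed=3)
        assert stats.morans_i > 0.5
        assert stats.p_value <= 0.01

    def test_random_labels_are_incoherent(self):
        coords = square_coords(10)
        w = build_adjacency(coords)
        rng = np.random.default_rng(5)
        labels = pd.Series(rng.integers(1, 4, size=100), index=coords.index)
        stats = morans_i_categorical(labels, w, n_permutations=99, seed=5)
        assert abs(stats.morans_i) < 0.15

    def test_relabelling_preserves_statistic(self):
        coords = square_coords(4)
        w = build_adjacency(coords)
        labels = pd.Series([1 if p % 4 < 2 else 2 for p in range(16)],
                           index=coords.index)
        swapped = labels.map({1: 2, 2: 1})
        a = morans_i_categorical(labels, w, n_permutations=49, seed=1)
        b = morans_i_categorical(swapped, w, n_permutations=49, seed=1)
        assert a.morans_i == pytest.approx(b.morans_i, abs=1e-12)

    def test_single_region_rejected(self):
        w = build_adjacency(square_coords(2))
        with pytest.raises(DataError):
            morans_i_categorical(pd.Series([1, 1, 1, 1], index=range(4)), w)

    def test_p_value_reproducible(self):
        coords = square_coords(4)
        w = build_adjacency(coords)
        labels = pd.Series([1 if p // 4 < 2 else 2 for p in range(16)],
                           index=coords.index)
        a = morans_i_categorical(labels, w, n_permutations=199, seed=11)
        b = morans_i_categorical(labels, w, n_permutations=199, seed=11)
        assert 0 < a.p_value <= 1
        assert a.p_value == b.p_value


# Published cross-tabulation of five flora-derived regions against a
# vegetation-based reference map (pixel counts per cell).
TABLE2_COUNTS = {
    "Alpine": {"Alpine": 35, "Atlantic": 1, "Boreal": 1},
    "Atlantic": {"Atlantic": 151, "Continental": 31, "Mediterranean": 10, "Alpine": 4},
    "Boreal": {"Boreal": 105, "Alpine": 14},
    "Continental": {"Continental": 85, "Boreal": 15, "Alpine": 13, "Atlantic": 11,
                    "Mediterranean": 2, "Pannonian": 1},
    "Mediterranean": {"Mediterranean": 150, "Macaronesian": 16, "Atlantic": 2,
                      "Continental": 2},
}


class TestConfusion:
    def test_identical_maps_are_diagonal(self):
        labels = pd.Series([1, 1, 2, 2], index=range(4))
        table = confusion(labels, labels)
        assert np.trace(table.counts.to_numpy()) == 4

    def test_disjoint_labelings_have_zero_diagonal(self):
        a = pd.Series(["x", "x"], index=[0, 1])
        b = pd.Series(["y", "y"], index=[0, 1])
        table = confusion(a, b)
        assert np.trace(table.counts.to_numpy()) == 0

    def test_published_cross_tabulation_sums_to_649(self):
        table = ConfusionTable.from_counts(TABLE2_COUNTS)
        assert table.N == 649

    def test_empty_intersection_rejected(self):
        with pytest.raises(InputError):
            confusion(pd.Series([1], index=[0]), pd.Series([1], index=[9]))


class TestOverlapAndKappa:
    def test_published_overlap_values(self):
        table = ConfusionTable.from_counts(TABLE2_COUNTS)
        assert overlap_percent(table, "Alpine") == pytest.approx(94.59, abs=0.01)
        assert overlap_percent(table, "Continental") == pytest.approx(66.93, abs=0.01)

    def test_identity_overlap_is_100(self):
        table = confusion(pd.Series([1, 2], index=[0, 1]),
                          pd.Series([1, 2], index=[0, 1]))
        assert overlap_percent(table, 1) == 100.0

    def test_kappa_closed_forms(self):
        diag = ConfusionTable(pd.DataFrame([[2, 0], [0, 2]]))
        indep = ConfusionTable(pd.DataFrame([[1, 1], [1, 1]]))
        hand = ConfusionTable(pd.DataFrame([[2, 1], [0, 2]]))
        assert cohen_kappa(diag) == pytest.approx(1.0)
        assert cohen_kappa(indep) == pytest.approx(0.0)
        assert cohen_kappa(hand) == pytest.approx(0.61538, abs=1e-5)

    def test_kappa_matches_independent_implementation(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 60)
        b = np.where(rng.random(60) < 0.6, a, rng.integers(0, 3, 60))
        table = confusion(pd.Series(a), pd.Series(b))
        assert cohen_kappa(table) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_per_category_collapse(self):
        table = ConfusionTable(pd.DataFrame([[2, 1], [0, 2]]))
        assert per_category_kappa(table, 0) == pytest.approx(0.61538, abs=1e-5)
        indep = ConfusionTable(pd.DataFrame([[1, 1], [1, 1]]))
        assert per_category_kappa(indep, 0) == pytest.approx(0.0)
        ident = confusion(pd.Series([1, 2], index=[0, 1]),
                          pd.Series([1, 2], index=[0, 1]))
        assert per_category_kappa(ident, 1) == pytest.approx(1.0)

    def test_category_permutation_invariance(self):
        table = ConfusionTable.from_counts(TABLE2_COUNTS)
        cats = table.categories
        perm = cats[1:] + cats[:1]
        permuted = ConfusionTable(table.counts.loc[perm, perm])
        assert cohen_kappa(permuted) == pytest.approx(cohen_kappa(table), abs=1e-12)
        assert overlap_percent(permuted, "Alpine") == overlap_percent(table, "Alpine")

    def test_degenerate_single_category_rejected(self):
        with pytest.raises(DataError):
            cohen_kappa(ConfusionTable(pd.DataFrame([[4]])))


class TestAgreementLabel:
    @pytest.mark.parametrize("kappa,label", [
        (0.709, "very good"), (0.1, "very poor"), (0.85, "excellent"),
        (0.2, "poor"), (0.4, "fair"), (0.55, "good"), (0.6999, "good"),
        (0.7, "very good"), (-0.3, "very poor"), (1.0, "excellent"),
    ])
    def test_bands(self, kappa, label):
        assert agreement_label(kappa) == label


class TestCrossSchemeOverlap:
    def test_relabelled_partitions_match_fully(self):
        a = pd.Series([1, 1, 2, 2], index=range(4))
        b = pd.Series([2, 2, 1, 1], index=range(4))
        assert cross_scheme_overlap(a, b) == 100.0

    def test_crossed_partition_is_half(self):
        a = pd.Series([1, 1, 2, 2], index=range(4))
        b = pd.Series([1, 2, 1, 2], index=range(4))
        assert cross_scheme_overlap(a, b) == 50.0

    def test_self_overlap_and_symmetry(self):
        rng = np.random.default_rng(1)
        a = pd.Series(rng.integers(1, 4, 30), index=range(30))
        b = pd.Series(rng.integers(1, 4, 30), index=range(30))
        assert cross_scheme_overlap(a, a) == 100.0
        assert cross_scheme_overlap(a, b) == cross_scheme_overlap(b, a)
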