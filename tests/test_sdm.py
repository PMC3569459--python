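"""Maxent-style suitability model: features, fit, projection, evaluation,
thresholding, and the species-level filters."""

import math

import numpy as np
import pytest

from bioregionize.assembly import OccurrenceTable
from bioregionize.errors import DataError, EvaluationError, InputError, StateError
from bioregionize.sdm import (MaxentSuitability, auc, build_features,
                              evaluate_replicates, filter_by_auc,
                              filter_species, fit_maxent, predict,
                              threshold_max_ss, SuitabilityModel)

from conftest import grid_from


class TestFeatures:
    def test_linear_features_are_minmax_scaled(self, line_grid):
        F, names, _ = build_features(line_grid)
        np.testing.assert_allclose(F[:, 0], [0, 0.5, 1])
        np.testing.assert_allclose(F[:, 1], [0, 0.25, 1])
        assert names == ["x", "x^2"]

    def test_linear_only_feature_count(self):
        from bioregionize.sdm import FeatureSpec
        grid = grid_from(np.array([[0, 1], [1, 2], [2, 0]], float))
        F, names, _ = build_features(grid, FeatureSpec(kinds=("linear",)))
        assert F.shape[1] == 2

    def test_constant_variable_is_a_data_error(self):
        grid = grid_from(np.array([[1.0], [1.0], [1.0]]))
        with pytest.raises(DataError):
            build_features(grid)


class TestFitMaxent:
    def test_presences_everywhere_give_uniform_model(self):
        F = np.array([[0.0], [0.5], [1.0]])
        model = fit_maxent([0, 1, 2], F, beta=2.0)
        np.testing.assert_allclose(list(model.weights.values()), 0.0, atol=1e-12)
        p = model.estimator.gibbs_probabilities(F)
        np.testing.assert_allclose(p, 1 / 3)

    def test_single_presence_matches_grid_search_oracle(self):
        F = np.array([[0.0], [0.5], [1.0]])
        model = fit_maxent([2], F, beta=0.0, max_iter=5000, tol=1e-10)

        def objective(w):
            z = F[:, 0] * w
            return w * 1.0 - (np.log(np.exp(z).sum()))

        grid = np.linspace(-5, 50, 22001)
        best = max(objective(w) for w in grid)
        ours = model.estimator.objective_path_[-1]
        assert ours >= best - 1e-3
        p = model.estimator.gibbs_probabilities(F)
        assert p[2] > 0.98

    def test_huge_penalty_forces_zero_weights(self):
        F = np.array([[0.0, 1.0], [0.5, 0.2], [1.0, 0.7]])
        model = fit_maxent([2], F, beta=1e6)
        np.testing.assert_array_equal(list(model.weights.values()), [0.0, 0.0])
        np.testing.assert_allclose(
            model.estimator.gibbs_probabilities(F), 1 / 3)

    def test_saturated_indicator_model_recovers_empirical_frequencies(self):
        F = np.eye(4)
        presences = [0] + [1] * 2 + [2] * 3 + [3] * 4
        model = fit_maxent(presences, F, beta=0.0, max_iter=20000, tol=1e-12)
        p = model.estimator.gibbs_probabilities(F)
        np.testing.assert_allclose(p, [0.1, 0.2, 0.3, 0.4], atol=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_path_is_monotone_and_gibbs_normalized(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((40, 6))
        presences = rng.choice(40, size=12, replace=False)
        model = fit_maxent(presences, F, beta=2.0)
        path = model.estimator.objective_path_
        assert np.all(np.diff(path) >= -1e-12)
        assert model.estimator.gibbs_probabilities(F).sum() == pytest.approx(1.0, abs=1e-10)

    def test_no_presences_rejected(self):
        with pytest.raises(InputError):
            fit_maxent([], np.eye(3))

    def test_non_finite_features_rejected(self):
        F = np.array([[0.0], [np.nan], [1.0]])
        with pytest.raises(DataError):
            fit_maxent([0], F)


class TestPredict:
    def test_zero_weights_give_uniform_map(self):
        F = np.array([[0.0], [0.5], [1.0]])
        model = fit_maxent([0, 1, 2], F)
        smap = predict(model, F)
        np.testing.assert_allclose(list(smap.values.values()), 1.0)

    def test_hand_computed_rescaled_gibbs(self):
        est = MaxentSuitability().fit(np.array([[0.0], [0.5], [1.0]]),
                                      np.array([0, 0, 1]))
        est.coef_ = np.array([1.0])  # fixed weight, hand-checkable
        model = SuitabilityModel("sp", {"x": 1.0}, 2.0, 0.0, estimator=est)
        smap = predict(model, np.array([[0.0], [0.5], [1.0]]))
        np.testing.assert_allclose(
            list(smap.values.values()),
            [math.exp(-1), math.exp(-0.5), 1.0], atol=1e-12)

    def test_monotone_in_single_positive_weight(self):
        est = MaxentSuitability().fit(np.array([[0.0], [0.5], [1.0]]),
                                      np.array([0, 0, 1]))
        est.coef_ = np.array([2.5])
        vals = est.predict_suitability(np.array([[0.1], [0.4], [0.9]]))
        assert np.all(np.diff(vals) > 0)

    def test_dimension_mismatch_rejected(self):
        model = fit_maxent([0], np.eye(3))
        with pytest.raises(InputError):
            predict(model, np.zeros((3, 5)))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.4, 0.2]) == 1.0

    def test_half_concordant(self):
        assert auc([0.9, 0.2], [0.3, 0.6]) == pytest.approx(0.5)

    def test_all_tied_is_half(self):
        assert auc([0.5], [0.5]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            auc([], [0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        pres = rng.choice([0.1, 0.3, 0.5, 0.7], size=rng.integers(2, 30))
        bg = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 40))
        pairs = sum((1.0 if p > b else 0.5 if p == b else 0.0)
                    for p in pres for b in bg)
        assert auc(pres, bg) == pytest.approx(pairs / (len(pres) * len(bg)), abs=1e-12)


class TestThreshold:
    def test_clean_split(self):
        assert threshold_max_ss([0.8, 0.6], [0.5, 0.1]) == pytest.approx(0.6)

    def test_degenerate_tie(self):
        assert threshold_max_ss([0.9], [0.9]) == pytest.approx(0.9)

    def test_partial_overlap(self):
        assert threshold_max_ss([0.7, 0.3], [0.5]) == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        pres = rng.random(rng.integers(1, 20))
        bg = rng.random(rng.integers(1, 30))
        candidates = np.unique(np.concatenate([pres, bg]))
        best_t, best_sum = None, -1.0
        for t in candidates:  # ascending, so ties keep the smallest
            s = (pres >= t).mean() + (bg < t).mean()
            if s > best_sum + 1e-12:
                best_t, best_sum = t, s
        assert threshold_max_ss(pres, bg) == pytest.approx(best_t)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            threshold_max_ss([], [0.5])


class TestReplicates:
    def test_presences_at_gradient_peak_score_high_auc(self):
        # test presences are themselves background pixels, so the AUC of a
        # perfect ranking stays a little below 1
        x = np.linspace(0, 1, 200)
        F = np.column_stack([x, x**2])
        presences = np.arange(190, 200)
        mean_auc, reps = evaluate_replicates(presences, F, beta=2.0, seed=1)
        assert len(reps) == 10
        assert min(reps) >= 0.95

    def test_same_seed_reproduces_replicates(self):
        x = np.linspace(0, 1, 20)
        F = np.column_stack([x, x**2])
        a = evaluate_replicates(range(10, 16), F, seed=7)
        b = evaluate_replicates(range(10, 16), F, seed=7)
        assert a == b

    def test_too_few_presences_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate_replicates([0, 1, 2], np.eye(5), seed=0)


class TestFilters:
    def test_occurrence_filter_is_strictly_greater(self):
        records = [("ten", p) for p in range(10)] + [("eleven", p) for p in range(11)]
        table = OccurrenceTable.from_records(records)
        assert filter_species(table, 10) == ["eleven"]

    def test_empty_table_gives_empty_list(self):
        table = OccurrenceTable.from_records([])
        assert filter_species(table) == []

    def test_auc_filter_boundary(self):
        def model(a):
            m = SuitabilityModel("s", {}, 2.0, 0.0)
            m.auc_mean = a
            return m
        kept = filter_by_auc([model(0.69), model(0.70), model(1.0)], 0.70)
        assert [m.auc_mean for m in kept] == [0.70, 1.0]

    def test_unevaluated_model_is_a_state_error(self):
        with pytest.raises(StateError):
            filter_by_auc([SuitabilityModel("s", {}, 2.0, 0.0)])
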