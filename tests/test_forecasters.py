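"""RBFN forecaster estimators, attractor ranking, fusion and MVE."""

import numpy as np
import pytest
from sklearn.base import clone

import arrbfn as ar
from arrbfn.forecasters import (
    ARRBFNForecaster,
    LibrarySpec,
    MVEForecaster,
    RBFNForecaster,
    fit_best_multivariate_rbfn,
    fit_univariate_rbfn,
    rank_embeddings,
    select_top_k,
)

IN_SAMPLE = (501, 2000)


@pytest.fixture(scope="module")
def X_in(noisy_ts):
    return noisy_ts.window(IN_SAMPLE)


@pytest.fixture(scope="module")
def X_test(noisy_ts):
    return noisy_ts.window((2501, 3000))


class TestRBFNForecaster:
    def test_constant_series_predicts_the_constant(self):
        X = np.full((40, 2), 3.7)
        est = RBFNForecaster(specs=["0:0,0:1,1:0"], target=0, random_state=0)
        est.fit(X)
        np.testing.assert_allclose(est.predict(X), 3.7, atol=1e-6)

    def test_prediction_invariant_to_center_and_weight_permutation(self, X_in, X_test):
        est = RBFNForecaster(specs=["1:0,0:0,2:1"], target=1, random_state=3)
        est.fit(X_in[:80])
        baseline = est.predict(X_test)
        perm = np.random.default_rng(0).permutation(est.layers_[0].p)
        est.layers_[0].centers = est.layers_[0].centers[perm]
        est.weights_ = est.weights_[perm]
        np.testing.assert_allclose(est.predict(X_test), baseline, atol=1e-10)

    def test_default_specs_are_target_own_lags(self, X_in):
        est = RBFNForecaster(target=2, embedding_dim=3).fit(X_in[:60])
        assert est.specs_[0].coords == ((2, 0), (2, 1), (2, 2))

    def test_missing_lags_at_requested_time_rejected(self, X_in):
        est = RBFNForecaster(target=0, random_state=0).fit(X_in[:60])
        with pytest.raises(ValueError, match="anchor"):
            est.predict_at(X_in[:60], np.array([1]))

    def test_empty_anchor_list_gives_empty_predictions(self, X_in):
        est = RBFNForecaster(target=0, random_state=0).fit(X_in[:60])
        assert est.predict_at(X_in[:60], np.array([], dtype=int)).size == 0

    def test_sklearn_clone_round_trip(self):
        est = RBFNForecaster(specs=["0:0,1:1"], target=1, ridge=0.5, random_state=9)
        params = clone(est).get_params()
        assert params["ridge"] == 0.5 and params["specs"] == ["0:0,1:1"]

    def test_window_too_short_to_fit(self):
        with pytest.raises(ValueError, match="too short"):
            RBFNForecaster(target=0).fit(np.random.default_rng(0).random((3, 2)))


class TestRanking:
    def test_three_variable_ranking_covers_all_64_manifolds(self, noisy_ts):
        lib = LibrarySpec(start=700, length=100, interval=IN_SAMPLE)
        ranked = rank_embeddings(noisy_ts, None, "y", lib, random_state=1)
        assert len(ranked) == 64
        assert [r.rank for r in ranked] == list(range(1, 65))
        skills = [r.skill for r in ranked]
        assert skills == sorted(skills, reverse=True)

    def test_ranking_is_deterministic(self, noisy_ts):
        lib = LibrarySpec(start=900, length=50, interval=IN_SAMPLE)
        a = rank_embeddings(noisy_ts, None, "y", lib, random_state=4)
        b = rank_embeddings(noisy_ts, None, "y", lib, random_state=4)
        assert [(r.spec, r.skill) for r in a] == [(r.spec, r.skill) for r in b]

    def test_informative_manifold_outranks_random_walk_decoy(self, logistic_ts):
        rng = np.random.default_rng(11)
        walk = np.cumsum(rng.normal(scale=0.05, size=logistic_ts.T))
        values = np.column_stack([logistic_ts.values, walk])
        ts = ar.TimeSeriesSet(values, ("x", "y", "z", "w"))
        lib = LibrarySpec(start=700, length=100, interval=IN_SAMPLE)
        # y' is a function of (x, y); the decoy manifold sees only the walk
        ranked = rank_embeddings(
            ts, ["0:0,1:0", "3:0,3:1"], "y", lib, random_state=2
        )
        assert ranked[0].spec.to_string(ts.names) == "x:0,y:0"
        assert ranked[0].skill > ranked[1].skill

    def test_single_spec_gets_rank_one(self, noisy_ts):
        lib = LibrarySpec(start=800, length=60, interval=IN_SAMPLE)
        ranked = rank_embeddings(noisy_ts, ["1:0,0:1"], "y", lib, random_state=0)
        assert len(ranked) == 1 and ranked[0].rank == 1

    def test_select_top_k(self, noisy_ts):
        lib = LibrarySpec(start=700, length=80, interval=IN_SAMPLE)
        ranked = rank_embeddings(noisy_ts, None, "y", lib, random_state=1)
        top3 = select_top_k(ranked, 3)
        assert top3 == [r.spec for r in ranked[:3]]
        assert select_top_k(ranked, len(ranked)) == [r.spec for r in ranked]
        with pytest.raises(ValueError):
            select_top_k(ranked, len(ranked) + 1)


class TestARRBFN:
    def test_top_k_defaults_to_number_of_variables(self, X_in):
        est = ARRBFNForecaster(target=1, random_state=0)
        est.fit(X_in, library=(200, 100))
        assert est.k_ == 3 and len(est.top_specs_) == 3

    def test_k1_identical_to_best_multivariate_wrapper(self, noisy_ts, X_in, X_test):
        lib = LibrarySpec(start=701, length=100, interval=IN_SAMPLE)
        fused = ARRBFNForecaster(target=1, top_k=1, random_state=5)
        fused.fit(X_in, library=(200, 100))
        direct = fit_best_multivariate_rbfn(noisy_ts, "y", lib, random_state=5)
        np.testing.assert_allclose(
            fused.predict(X_test), direct.predict(X_test), atol=1e-10
        )

    def test_duplicated_manifold_leaves_training_predictions_unchanged(self, X_in):
        # with (near-)minimum-norm solving, duplicating a kernel block splits
        # its weights without changing the fitted function
        lib = X_in[200:300]
        single = RBFNForecaster(
            specs=["1:0,0:0,2:1"], target=1, n_centers=8, ridge=1e-9, random_state=7
        )
        double = RBFNForecaster(
            specs=["1:0,0:0,2:1", "1:0,0:0,2:1"], target=1, n_centers=8,
            ridge=1e-9, random_state=7,
        )
        np.testing.assert_allclose(
            single.fit(lib).predict(lib), double.fit(lib).predict(lib), atol=1e-6
        )

    def test_noise_free_in_sample_skill_above_099(self, logistic_ts):
        X_in = logistic_ts.window(IN_SAMPLE)
        est = ARRBFNForecaster(target=1, random_state=3)
        est.fit(X_in, library=(400, 100))
        preds, obs, _ = est.forecast(X_in[400:500])
        assert ar.pearson_correlation(preds, obs) > 0.99

    def test_forecast_never_touches_the_gap(self, noisy_ts, X_test):
        # predictions on the test window depend only on the library fit and
        # the test rows themselves
        est = ARRBFNForecaster(target=1, random_state=1)
        est.fit(noisy_ts.window(IN_SAMPLE), library=(100, 100))
        preds, obs, times0 = est.forecast(X_test)
        assert times0[0] == 3 and len(preds) == 497
        corrupted = X_test.copy()
        est2_preds = est.predict_at(corrupted, np.arange(2, 499))
        np.testing.assert_allclose(est2_preds, preds)

    def test_forecast_wrapper_with_empty_times(self, noisy_ts):
        lib = LibrarySpec(start=700, length=100, interval=IN_SAMPLE)
        model = ar.fit_arrbfn(noisy_ts, ["1:0,0:1"], "y", lib, random_state=0)
        assert ar.forecast(model, noisy_ts, []).size == 0


class TestUnivariateBaseline:
    def test_univariate_manifold_is_target_lags(self, noisy_ts):
        lib = LibrarySpec(start=700, length=100, interval=IN_SAMPLE)
        est = fit_univariate_rbfn(noisy_ts, "y", lib, random_state=0)
        assert est.specs_[0].coords == ((1, 0), (1, 1), (1, 2))

    def test_decoupled_system_makes_univariate_near_perfect(self):
        # with zero interspecific coupling each variable is a closed
        # 1-D logistic map, so its own lags suffice
        params = ar.CoupledLogisticParams(cxz=0.0, cyx=0.0, czy=0.0)
        ts = ar.simulate_coupled_logistic(params, initial_state=(0.41, 0.53, 0.47))
        part = ar.make_partition(ts)
        lib = LibrarySpec(start=700, length=100, interval=part.in_sample)
        est = fit_univariate_rbfn(ts, "y", lib, random_state=0)
        preds, obs, _ = est.forecast(ts.window(part.test))
        assert ar.pearson_correlation(preds, obs) > 0.99

    def test_deterministic_given_seed(self, noisy_ts, X_test):
        lib = LibrarySpec(start=900, length=50, interval=IN_SAMPLE)
        a = fit_univariate_rbfn(noisy_ts, "y", lib, random_state=3).predict(X_test)
        b = fit_univariate_rbfn(noisy_ts, "y", lib, random_state=3).predict(X_test)
        np.testing.assert_array_equal(a, b)


class TestMVE:
    def test_retains_sqrt_of_valid_embeddings(self, X_in):
        est = MVEForecaster(target=1).fit(X_in, library=(200, 100))
        assert len(est.views_) == 8  # ceil(sqrt(64))

    def test_exact_library_match_returns_observed_next_value(self, logistic_ts):
        X_in = logistic_ts.window(IN_SAMPLE)
        est = MVEForecaster(target=1).fit(X_in, library=(0, 200))
        # an anchor inside the library matches its own delay vector exactly
        t = 50
        pred = est.predict_at(X_in, np.array([t]))[0]
        assert pred == pytest.approx(X_in[t + 1, 1], abs=1e-12)

    def test_constant_series_predicts_the_constant(self):
        X = np.full((40, 3), 0.25)
        est = MVEForecaster(target=0).fit(X)
        np.testing.assert_allclose(est.predict(X), 0.25, atol=1e-12)

    def test_predictions_bounded_by_library_target_range(self, X_in, X_test):
        est = MVEForecaster(target=1).fit(X_in, library=(300, 60))
        preds = est.predict(X_test)
        lo, hi = est.library_targets_.min(), est.library_targets_.max()
        assert np.all(preds >= lo - 1e-12) and np.all(preds <= hi + 1e-12)
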