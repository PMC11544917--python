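import numpy as np
import pytest

import oracles
from glucluster.clustering import ClusterModel, fit_cluster_model
from glucluster.exceptions import ConfigurationError, DataError
from glucluster.forecasters import (
    DEFAULT_HOLT_GRID,
    HoltParams,
    HorizonSpec,
    cluster_weights,
    fit_cluster_routed,
    fit_global,
    holt_fit,
    holt_forecast,
    load_model,
    mtsc_forecast,
    predict_cluster_routed,
    save_model,
    wmtsc_forecast,
)


def manual_model(medoids):
    medoids = np.asarray(medoids, dtype=float)
    k = medoids.shape[0]
    return ClusterModel(
        k=k, labels=np.arange(1, k + 1), medoid_ids=np.arange(k),
        medoid_series=medoids,
    )


def random_medoid_instance(rng, k=None, length=12, h=3):
    k = k or int(rng.integers(2, 6))
    medoids = rng.uniform(3, 15, size=(k, length))
    prefix = rng.uniform(3, 15, size=length - h)
    return manual_model(medoids), prefix, HorizonSpec(5 * h)


class TestHorizon:
    def test_steps(self):
        assert HorizonSpec(15).steps == 3
        assert HorizonSpec(30).steps == 6

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            HorizonSpec(7)


class TestMTSC:
    def test_single_cluster_ignores_prefix(self):
        model = manual_model([[5.0, 6.0, 7.0, 8.0]])
        out = mtsc_forecast(np.array([20.0, 20.0]), model, HorizonSpec(10))
        np.testing.assert_array_equal(out, [7.0, 8.0])

    def test_exact_prefix_match_selects_that_medoid(self):
        model = manual_model([[5.0, 5.0, 5.2, 5.3], [8.0, 8.0, 8.1, 8.2]])
        out = mtsc_forecast(np.array([8.0, 8.0]), model, HorizonSpec(10))
        np.testing.assert_array_equal(out, [8.1, 8.2])

    def test_nearest_medoid_arithmetic(self):
        model = manual_model([[5.0, 5.0, 5.0, 5.2], [8.0, 8.0, 8.0, 8.1]])
        out = mtsc_forecast(np.array([5.5, 5.4, 5.6]), model, HorizonSpec(5))
        np.testing.assert_array_equal(out, [5.2])

    def test_output_is_a_stored_medoid_tail(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            model, prefix, horizon = random_medoid_instance(rng)
            out = mtsc_forecast(prefix, model, horizon)
            tails = model.medoid_series[:, -horizon.steps:]
            assert any(np.array_equal(out, t) for t in tails)

    def test_horizon_too_long(self):
        model = manual_model([[5.0, 6.0]])
        with pytest.raises(ConfigurationError):
            mtsc_forecast(np.array([5.0]), model, HorizonSpec(10))


class TestWMTSC:
    def test_equidistant_gives_uniform_average(self):
        model = manual_model([[4.0, 4.0, 4.0, 4.0], [6.0, 6.0, 8.0, 8.0]])
        out = wmtsc_forecast(np.array([5.0, 5.0]), model, HorizonSpec(10))
        np.testing.assert_allclose(out, [6.0, 6.0])

    def test_weights_and_forecast_hand_values(self):
        # prefix at distance 1 from medoid 1 and 2 from medoid 2
        model = manual_model([[5.0, 4.0, 4.0, 4.0], [8.0, 8.0, 8.0, 8.0]])
        prefix = np.array([6.0])
        a = cluster_weights(prefix, model)
        np.testing.assert_allclose(a.distances, [1.0, 2.0])
        np.testing.assert_allclose(a.weights, [0.622459, 0.377541], atol=1e-6)
        out = wmtsc_forecast(prefix, model, HorizonSpec(15))
        np.testing.assert_allclose(out, [5.510164] * 3, atol=1e-5)

    def test_zero_distance_shortcut(self):
        model = manual_model([[5.0, 5.0, 5.2, 5.3], [8.0, 8.0, 8.1, 8.2]])
        out = wmtsc_forecast(np.array([5.0, 5.0]), model, HorizonSpec(10))
        np.testing.assert_array_equal(out, [5.2, 5.3])

    def test_ties_among_zero_distances_average_uniformly(self):
        model = manual_model([[5.0, 5.0, 4.0, 4.0], [5.0, 5.0, 6.0, 6.0]])
        out = wmtsc_forecast(np.array([5.0, 5.0]), model, HorizonSpec(10))
        np.testing.assert_allclose(out, [5.0, 5.0])

    def test_weights_sum_to_one_and_convex_envelope(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            model, prefix, horizon = random_medoid_instance(rng)
            a = cluster_weights(prefix, model)
            assert np.all(a.weights >= 0)
            assert abs(a.weights.sum() - 1.0) <= 1e-9
            out = wmtsc_forecast(prefix, model, horizon)
            tails = model.medoid_series[:, -horizon.steps:]
            assert np.all(out >= tails.min(axis=0) - 1e-12)
            assert np.all(out <= tails.max(axis=0) + 1e-12)

    def test_converges_to_mtsc_as_distance_vanishes(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            model, prefix, horizon = random_medoid_instance(rng)
            j = int(rng.integers(model.k))
            # place the prefix 1e-8 away from medoid j's prefix
            prefix = model.medoid_series[j, : len(prefix)].copy()
            prefix[0] += 1e-8
            w = wmtsc_forecast(prefix, model, horizon)
            m = mtsc_forecast(prefix, model, horizon)
            np.testing.assert_allclose(w, m, atol=1e-6)


class TestHolt:
    def test_constant_prefix(self):
        out = holt_forecast(np.full(20, 6.0), HoltParams(0.3, 0.7), HorizonSpec(30))
        np.testing.assert_allclose(out, 6.0, atol=1e-12)

    def test_linear_prefix_exact_with_unit_weights(self):
        t = np.arange(1, 31)
        y = 4.0 + 0.1 * t
        out = holt_forecast(y, HoltParams(1.0, 1.0), HorizonSpec(30))
        expected = 4.0 + 0.1 * (30 + np.arange(1, 7))
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_hand_traced_recursion(self):
        out = holt_forecast(np.array([5.0, 5.5, 5.3]), HoltParams(0.5, 0.5), HorizonSpec(5))
        assert out[0] == pytest.approx(5.975, abs=1e-12)

    def test_too_short_prefix(self):
        with pytest.raises(DataError):
            holt_forecast(np.array([5.0]), HoltParams(0.5, 0.5), HorizonSpec(5))

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        y = 6 + rng.normal(0, 0.5, 30)
        p = HoltParams(0.4, 0.2)
        base = holt_forecast(y, p, HorizonSpec(15))
        shifted = holt_forecast(y + 3.0, p, HorizonSpec(15))
        np.testing.assert_allclose(shifted, base + 3.0, atol=1e-9)


class TestHoltFit:
    def test_linear_series_unit_grid(self):
        y = 4.0 + 0.25 * np.arange(1, 21)
        params = holt_fit(y, alphas=[1.0], betas=[1.0])
        assert (params.alpha, params.beta) == (1.0, 1.0)

    def test_constant_series_ties_to_smallest(self):
        params = holt_fit(np.full(20, 6.0))
        assert (params.alpha, params.beta) == (0.1, 0.1)

    def test_attains_grid_minimum_vs_scalar_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            y = 6 + np.cumsum(rng.normal(0, 0.3, 25)) * 0.5
            params = holt_fit(y)
            best = min(
                oracles.holt_sse_oracle(y, a, b)
                for a in DEFAULT_HOLT_GRID
                for b in DEFAULT_HOLT_GRID
            )
            got = oracles.holt_sse_oracle(y, params.alpha, params.beta)
            assert got <= best + 1e-9


@pytest.fixture(scope="module")
def trend_cohort():
    """Two well-separated constant-level groups, light noise."""
    rng = np.random.default_rng(23)
    low = 5.0 + rng.normal(0, 0.1, size=(30, 24))
    high = 12.0 + rng.normal(0, 0.1, size=(30, 24))
    return np.vstack([low, high])


class TestSupervised:
    def test_constant_cluster_predicts_constant(self):
        train = np.full((12, 24), 6.0)
        model = manual_model([train[0]])
        model.labels = np.ones(12, dtype=int)
        routed = fit_cluster_routed(train, model, "random_forest", HorizonSpec(15), seed=0)
        pred = predict_cluster_routed(routed, np.full(21, 6.0))
        np.testing.assert_allclose(pred, 6.0, atol=1e-6)

    def test_global_constant(self):
        train = np.full((10, 24), 7.0)
        model = fit_global(train, "gradient_boosting", HorizonSpec(15), seed=0)
        np.testing.assert_allclose(
            model.predict(np.full(21, 7.0)[None, :]), 7.0, atol=1e-6
        )

    @pytest.mark.parametrize("kind", ["random_forest", "gradient_boosting"])
    def test_seeded_determinism(self, trend_cohort, kind):
        horizon = HorizonSpec(15)
        cm = fit_cluster_model(trend_cohort, k=2)
        test_prefix = trend_cohort[:5, :-3]
        a = fit_cluster_routed(trend_cohort, cm, kind, horizon, seed=4)
        b = fit_cluster_routed(trend_cohort, cm, kind, horizon, seed=4)
        np.testing.assert_array_equal(
            predict_cluster_routed(a, test_prefix), predict_cluster_routed(b, test_prefix)
        )

    def test_k1_cluster_routed_equals_global(self, trend_cohort):
        """With a single cluster the routed model is structurally the global one."""
        horizon = HorizonSpec(30)
        cm = manual_model([trend_cohort[0]])
        cm.labels = np.ones(trend_cohort.shape[0], dtype=int)
        routed = fit_cluster_routed(
            trend_cohort, cm, "gradient_boosting", horizon, seed=9
        )
        glob = fit_global(trend_cohort, "gradient_boosting", horizon, seed=9)
        prefixes = trend_cohort[::7, :-6]
        np.testing.assert_allclose(
            predict_cluster_routed(routed, prefixes), glob.predict(prefixes)
        )

    def test_routing_matches_assign_nearest(self, trend_cohort):
        from glucluster.clustering import assign_nearest_cluster

        horizon = HorizonSpec(15)
        cm = fit_cluster_model(trend_cohort, k=2)
        routed = fit_cluster_routed(trend_cohort, cm, "random_forest", horizon, seed=0)
        for prefix in trend_cohort[::11, :-3]:
            cid, _ = assign_nearest_cluster(prefix, cm)
            expected = np.asarray(
                routed.learners[cid].predict(prefix[None, :])
            ).ravel()
            np.testing.assert_allclose(
                predict_cluster_routed(routed, prefix), expected
            )

    def test_undersized_cluster_uses_fallback(self, trend_cohort):
        horizon = HorizonSpec(15)
        cm = fit_cluster_model(trend_cohort, k=2)
        routed = fit_cluster_routed(
            trend_cohort, cm, "random_forest", horizon, seed=0, min_cluster_size=40
        )
        assert routed.learners == {} and routed.fallback is not None
        pred = predict_cluster_routed(routed, trend_cohort[:3, :-3])
        assert pred.shape == (3, 3) and np.all(np.isfinite(pred))

    def test_predictions_within_extended_sensor_range(self, trend_cohort):
        horizon = HorizonSpec(30)
        cm = fit_cluster_model(trend_cohort, k=2)
        routed = fit_cluster_routed(trend_cohort, cm, "gradient_boosting", horizon, seed=2)
        pred = predict_cluster_routed(routed, cm.medoid_series[:, :-6])
        assert np.all(np.isfinite(pred))
        assert np.all(pred >= 2.2 * 0.8) and np.all(pred <= 22.2 * 1.2)

    def test_specialist_beats_global_on_its_pattern(self):
        """The reason cluster routing exists: a model trained on one pattern
        forecasts held-out nights of that pattern better than a model trained
        on the mixed cohort when patterns differ in their tails."""
        rng = np.random.default_rng(31)
        L, n = 24, 40
        t = np.arange(L)
        down = 10.0 + rng.normal(0, 2.5, (n, 1)) - 0.2 * t
        up = 5.0 + rng.normal(0, 2.5, (n, 1)) + 0.25 * t
        holdout = 10.0 + rng.normal(0, 2.5, (20, 1)) - 0.2 * t
        horizon = HorizonSpec(15)
        cm = manual_model([down.mean(axis=0)])
        cm.labels = np.ones(n, dtype=int)
        specialist = fit_cluster_routed(down, cm, "gradient_boosting", horizon, seed=1)
        glob = fit_global(np.vstack([down, up]), "gradient_boosting", horizon, seed=1)
        truth = holdout[:, -3:]
        mae_spec = np.mean(np.abs(predict_cluster_routed(specialist, holdout[:, :-3]) - truth))
        mae_glob = np.mean(np.abs(glob.predict(holdout[:, :-3]) - truth))
        assert mae_spec < mae_glob


def test_model_bundle_roundtrip(tmp_path, trend_cohort):
    horizon = HorizonSpec(15)
    model = fit_global(trend_cohort, "random_forest", horizon, seed=0)
    save_model(model, tmp_path / "m.joblib")
    back = load_model(tmp_path / "m.joblib")
    prefixes = trend_cohort[:4, :-3]
    np.testing.assert_array_equal(back.predict(prefixes), model.predict(prefixes))
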