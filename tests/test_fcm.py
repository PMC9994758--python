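"""Fuzzy c-means core and the fitted phenology model."""

import json

import numpy as np
import pandas as pd
import pytest

from phenofcm.fcm import fcm_objective, fit_fcm, memberships, _update_centers
from phenofcm.model import (
    PhenologyFCM,
    PhenologyFCMResults,
    assign_stage_order,
    build_baseline,
    compute_threshold,
    threshold_metaclass,
)
from phenofcm.stages import Metaclass, PhenologyStage

P = PhenologyStage


class TestMemberships:
    def test_point_on_center_gets_full_membership(self):
        centers = np.array([[0.0, 0.0], [3.0, 0.0]])
        W = memberships(centers, np.array([[3.0, 0.0]]), m=2.0)
        assert W[0, 1] == pytest.approx(1.0)
        assert W[0, 0] == pytest.approx(0.0)

    def test_equidistant_point_splits_evenly(self):
        # six centers on a regular hexagon, query at the origin
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        centers = np.c_[np.cos(ang), np.sin(ang)]
        W = memberships(centers, np.array([[0.0, 0.0]]), m=2.0)
        assert W[0] == pytest.approx(np.full(6, 1 / 6))

    def test_two_cluster_closed_form(self):
        centers = np.array([[0.0], [1.0]])
        x = np.array([[0.2]])
        W = memberships(centers, x, m=2.0)
        d1, d2 = 0.2, 0.8
        expected = 1.0 / (1.0 + (d1 / d2) ** 2)
        assert W[0, 0] == pytest.approx(expected)
        assert W.sum(axis=1) == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        centers = rng.normal(size=(6, 4))
        X = rng.normal(size=(50, 4))
        W = memberships(centers, X, m=2.0)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)


class TestFit:
    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        sd, n = 0.3, 150
        a = rng.normal([0, 0], sd, size=(n, 2))
        b = rng.normal([6, 6], sd, size=(n, 2))
        X = np.vstack([a, b])
        centers, W = fit_fcm(X, c=2, m=2.0, seed=0)
        order = np.argsort(centers[:, 0])
        tol = 3 * sd / np.sqrt(n)
        assert np.allclose(centers[order[0]], a.mean(axis=0), atol=tol)
        assert np.allclose(centers[order[1]], b.mean(axis=0), atol=tol)

    def test_objective_matches_brute_force_on_small_sample(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.2, size=(10, 2)), rng.normal(4, 0.2, size=(10, 2))]
        )
        centers, W = fit_fcm(X, c=2, m=2.0, seed=1)
        # brute-force oracle: explicit double sum over elements and clusters
        brute = 0.0
        for k in range(X.shape[0]):
            for l in range(2):
                brute += W[k, l] ** 2 * np.sum((X[k] - centers[l]) ** 2)
        assert fcm_objective(centers, X, W, 2.0) == pytest.approx(brute)

    def test_objective_non_increasing_over_iterations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        W = rng.random((60, 4))
        W /= W.sum(axis=1, keepdims=True)
        centers = _update_centers(X, W, 2.0)
        last = fcm_objective(centers, X, W, 2.0)
        for _ in range(25):
            W = memberships(centers, X, 2.0)
            centers = _update_centers(X, W, 2.0)
            obj = fcm_objective(centers, X, W, 2.0)
            assert obj <= last + 1e-9
            last = obj

    def test_converged_solution_is_fixed_point(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        centers, W = fit_fcm(X, c=3, m=2.0, seed=2)
        W2 = memberships(centers, X, 2.0)
        np.testing.assert_allclose(W, W2, atol=1e-6)
        np.testing.assert_allclose(centers, _update_centers(X, W2, 2.0), atol=1e-4)

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            fit_fcm(np.zeros((4, 2)), c=6)

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ValueError):
            fit_fcm(np.random.default_rng(0).normal(size=(20, 2)), c=2, m=1.0)


def partition_from_sequences(sequences):
    """Hard partition matrix + (field, doy) index from argmax sequences."""
    rows, idx = [], []
    for f, seq in enumerate(sequences):
        for j, cluster in enumerate(seq):
            w = np.full(6, 0.01)
            w[cluster] = 1 - 0.05
            rows.append(w / w.sum())
            idx.append((f"f{f}", 100 + 5 * j))
    index = pd.MultiIndex.from_tuples(idx, names=["field_id", "doy"])
    return np.array(rows), index


class TestStageOrder:
    def test_unanimous_order_maps_first_to_re(self):
        seq = [2, 2, 0, 4, 1, 5, 3]
        W, index = partition_from_sequences([seq] * 4)
        mapping, fallback = assign_stage_order(W, index)
        assert not fallback
        assert mapping[2] == P.RE
        assert mapping[0] == P.LD
        assert mapping[4] == P.S
        assert mapping[1] == P.F
        assert mapping[5] == P.BD
        assert mapping[3] == P.BO

    def test_modal_order_wins(self):
        a = [0, 1, 2, 3, 4, 5]
        b = [1, 0, 2, 3, 4, 5]
        W, index = partition_from_sequences([a] * 7 + [b] * 3)
        mapping, _ = assign_stage_order(W, index)
        assert mapping[0] == P.RE and mapping[1] == P.LD

    def test_fallback_orders_by_mean_doy(self):
        # no field shows all six clusters: each sees an incomplete sequence
        W, index = partition_from_sequences([[0, 1, 2], [3, 4, 5]])
        mapping, fallback = assign_stage_order(W, index)
        assert fallback
        assert mapping[0] == P.RE and mapping[5] == P.BO

    def test_recovers_generating_map_on_synthetic_partition(self):
        rng = np.random.default_rng(0)
        perm = rng.permutation(6)  # cluster labels in scrambled order
        seqs = []
        for _ in range(10):
            stages = np.repeat(np.arange(6), rng.integers(2, 5, size=6))
            seqs.append([perm[s] for s in stages])
        W, index = partition_from_sequences(seqs)
        mapping, fallback = assign_stage_order(W, index)
        assert not fallback
        assert {c: int(s) for c, s in mapping.items()} == {
            int(perm[s]): s + 1 for s in range(6)
        }


class TestThreshold:
    def test_constant_third_weights(self):
        W = np.tile([0.5, 0.3, 0.1, 0.06, 0.03, 0.01], (20, 1))
        assert compute_threshold(W) == pytest.approx(0.1)

    def test_matches_percentile_oracle_on_spread_values(self):
        thirds = np.linspace(0.0, 0.2, 100)
        rows = []
        for v in thirds:
            rows.append([0.5, 0.3, v, 0.0, 0.0, 0.0])
        W = np.array(rows)
        assert compute_threshold(W) == pytest.approx(np.percentile(thirds, 98))

    def test_needs_three_clusters(self):
        with pytest.raises(ValueError):
            compute_threshold(np.array([[0.6, 0.4]]))


class TestThresholdMetaclass:
    def ranking(self, weights, stages):
        return tuple((s, w) for s, w in zip(stages, weights))

    def test_adjacent_runner_up_above_threshold_becomes_secondary(self):
        r = self.ranking((0.80, 0.15, 0.05), (P.F, P.BD, P.S))
        mc, suppressed = threshold_metaclass(r, 0.11)
        assert mc == Metaclass(P.F, P.BD) and not suppressed

    def test_runner_up_below_threshold_gives_unit(self):
        r = self.ranking((0.90, 0.05, 0.05), (P.F, P.BD, P.S))
        mc, _ = threshold_metaclass(r, 0.11)
        assert mc == Metaclass(P.F)

    def test_threshold_is_strict(self):
        r = self.ranking((0.80, 0.11, 0.09), (P.F, P.BD, P.S))
        mc, _ = threshold_metaclass(r, 0.11)
        assert mc == Metaclass(P.F)

    def test_non_adjacent_runner_up_suppressed(self):
        r = self.ranking((0.60, 0.30, 0.10), (P.F, P.RE, P.S))
        mc, suppressed = threshold_metaclass(r, 0.11)
        assert mc == Metaclass(P.F) and suppressed


@pytest.fixture(scope="module")
def fitted(small_season):
    from phenofcm.features import assemble_element_space
    from phenofcm.pipeline import DEFAULT_FEATURE_SET

    X = assemble_element_space(
        small_season.bands, small_season.weather, list(DEFAULT_FEATURE_SET)
    )
    return X, PhenologyFCM(X).fit(seed=0)


class TestResults:
    def test_training_partition_is_prediction_fixed_point(self, fitted):
        X, res = fitted
        W = res.memberships(X)
        np.testing.assert_allclose(
            W.to_numpy(), res.train_partition.to_numpy(), atol=1e-6
        )

    def test_stage_map_is_bijection(self, fitted):
        _, res = fitted
        assert sorted(int(s) for s in res.cluster_to_stage.values()) == [1, 2, 3, 4, 5, 6]

    def test_threshold_in_open_interval(self, fitted):
        _, res = fitted
        assert 0.0 < res.th_w < 0.5

    def test_prediction_weights_descend_and_primary_matches(self, fitted):
        X, res = fitted
        for rec in res.predict_records(X.iloc[:50]):
            weights = [w for _, w in rec.ranking]
            assert weights == sorted(weights, reverse=True)
            assert rec.metaclass.primary == rec.ranking[0][0]

    def test_center_permutation_leaves_predictions_invariant(self, fitted):
        X, res = fitted
        perm = np.array([3, 0, 5, 1, 4, 2])
        permuted = PhenologyFCMResults(
            model=res.model,
            centers=res.centers[perm],
            scaler_mean=res.scaler_mean,
            scaler_scale=res.scaler_scale,
            cluster_to_stage={i: res.cluster_to_stage[int(p)] for i, p in enumerate(perm)},
            th_w=res.th_w,
            train_partition=None,
            seed=res.seed,
        )
        a = [r.metaclass for r in res.predict_records(X.iloc[:80])]
        b = [r.metaclass for r in permuted.predict_records(X.iloc[:80])]
        assert a == b

    def test_json_round_trip_is_bit_exact(self, fitted, tmp_path):
        X, res = fitted
        path = tmp_path / "model.json"
        res.save(path)
        loaded = PhenologyFCMResults.load(path)
        assert loaded.to_json() == res.to_json()
        a = res.predict(X.iloc[:40])
        b = loaded.predict(X.iloc[:40])
        pd.testing.assert_frame_equal(a, b)

    def test_future_schema_rejected(self, fitted):
        _, res = fitted
        payload = json.loads(res.to_json())
        payload["schema_version"] = "2.0"
        with pytest.raises(ValueError):
            PhenologyFCMResults.from_json(json.dumps(payload))

    def test_summary_reports_key_quantities(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "th_w" in text and "cluster" in text and "fuzzifier" in text


class TestBaseline:
    def test_baseline_has_two_features(self, small_season):
        model = build_baseline(small_season.bands)
        assert model.feature_names == ["sin_doy", "cos_doy"]

    def test_baseline_predictions_constant_across_fields_per_doy(self, small_season):
        model = build_baseline(small_season.bands)
        res = model.fit(seed=0)
        preds = res.predict(model.element_space)
        for _, grp in preds.groupby("doy"):
            assert grp["metaclass"].nunique() == 1
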