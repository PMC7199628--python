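"""Template scoring, the threshold decision rule, and model (de)serialization."""

import numpy as np
import pytest

from eegmatch.detector import (DetectorModel, TemplateSet, apply_model,
                               calibrate_detector, classify,
                               optimize_threshold, score_query)
from eegmatch.metrics import EPS_FLOOR, METRIC_NAMES, similarity


def make_templates(n=5, k=16, seed=0):
    gen = np.random.default_rng(seed)
    mat = gen.uniform(0.05, 1.0, (n, k))
    mat /= mat.sum(axis=1, keepdims=True)
    return TemplateSet(features=mat, source_ids=[f"t{i}" for i in range(n)])


class TestScoreQuery:
    def test_identical_template_is_maximal(self):
        templates = make_templates()
        q = templates.features[2]
        assert score_query(q, templates, "HD", "max") == 1.0 / EPS_FLOOR
        assert score_query(q, templates, "BD", "max") == pytest.approx(1.0)

    def test_single_template_ignores_aggregation(self):
        t = make_templates(n=1)
        q = np.full(16, 1 / 16)
        assert score_query(q, t, "HD", "max") == score_query(q, t, "HD", "min")

    @pytest.mark.parametrize("metric", METRIC_NAMES)
    @pytest.mark.parametrize("agg", ["max", "min"])
    def test_equals_exhaustive_aggregation(self, metric, agg):
        templates = make_templates()
        gen = np.random.default_rng(4)
        q = gen.uniform(0.05, 1, 16)
        q /= q.sum()
        sims = [similarity(metric, q, t) for t in templates.features]
        expected = max(sims) if agg == "max" else min(sims)
        assert score_query(q, templates, metric, agg) == expected

    def test_adding_template_is_monotone(self):
        gen = np.random.default_rng(9)
        q = gen.uniform(0.05, 1, 16)
        q /= q.sum()
        small = make_templates(n=4)
        extra = gen.uniform(0.05, 1, 16)
        big = TemplateSet(
            features=np.vstack([small.features, extra / extra.sum()]),
            source_ids=[*small.source_ids, "t-extra"])
        assert score_query(q, big, "HD", "max") >= score_query(q, small, "HD", "max")
        assert score_query(q, big, "HD", "min") <= score_query(q, small, "HD", "min")

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            score_query(np.ones(4) / 4, make_templates(), "HD")


class TestClassify:
    @pytest.mark.parametrize("s, lam, expected", [
        (0.8, 0.5, "normal"),
        (0.5, 0.5, "abnormal"),  # boundary belongs to the abnormal class
        (0.2, 0.5, "abnormal"),
    ])
    def test_threshold_rule(self, s, lam, expected):
        assert classify(s, lam) == expected

    def test_inputs_validated(self):
        with pytest.raises(ValueError):
            classify(1.5, 0.5)


SEPARATED_SCORES = np.array(
    [0.283, 0.117, 0.204, 0.252, 0.141, 0.762, 0.705, 0.913, 0.871, 0.834])
SEPARATED_LABELS = np.array(["abnormal"] * 5 + ["normal"] * 5)


class TestOptimizeThreshold:
    def test_perfect_separation(self):
        res = optimize_threshold(SEPARATED_SCORES, SEPARATED_LABELS, 0.01)
        assert res.best_accuracy == 1.0
        # optimum lies strictly between the two classes' score ranges
        assert 0.283 < res.lambda0 < 0.705
        assert res.best_accuracy == res.accuracies.max()
        # the optimum dominates every other grid point (by construction)
        assert np.all(res.accuracies <= res.best_accuracy)

    def test_curve_rises_then_falls_on_separated_scores(self):
        # with perfectly separated scores the accuracy-vs-lambda curve is
        # unimodal: nondecreasing up to the optimal plateau, nonincreasing after
        res = optimize_threshold(SEPARATED_SCORES, SEPARATED_LABELS, 0.01)
        assert res.accuracies[0] < res.best_accuracy
        assert res.accuracies[-1] < res.best_accuracy
        diffs = np.diff(res.accuracies)
        falling = np.flatnonzero(diffs < 0)
        rising = np.flatnonzero(diffs > 0)
        assert rising.size and falling.size
        assert rising.max() < falling.min()

    def test_random_labels_majority_bound(self, rng):
        scores = rng.uniform(0, 1, 40)
        labels = rng.choice(["normal", "abnormal"], 40)
        if len(set(labels)) < 2:
            labels[0] = "normal"
            labels[1] = "abnormal"
        res = optimize_threshold(scores, labels, 0.01)
        assert res.best_accuracy >= 0.5

    def test_exhaustive_grid_oracle(self):
        res = optimize_threshold(SEPARATED_SCORES, SEPARATED_LABELS, 0.1)
        is_abn = SEPARATED_LABELS == "abnormal"
        oracle = {
            lam: np.mean((SEPARATED_SCORES <= lam) == is_abn)
            for lam in np.linspace(0, 1, 11)
        }
        assert res.best_accuracy == max(oracle.values())
        assert oracle[res.lambda0] == res.best_accuracy

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            optimize_threshold([0.1, 0.9], ["normal", "normal"], 0.01)


class TestDetectorModel:
    def _calibrated(self):
        templates = make_templates(n=6, k=16, seed=1)
        gen = np.random.default_rng(10)
        normal = templates.features + gen.normal(0, 0.002, (6, 16))
        abnormal = gen.uniform(0.01, 1.0, (6, 16))
        feats = np.vstack([np.abs(normal), abnormal])
        feats /= feats.sum(axis=1, keepdims=True)
        labels = ["normal"] * 6 + ["abnormal"] * 6
        return calibrate_detector(templates, list(feats), labels, "HD")

    def test_template_query_classified_normal(self):
        model, _ = self._calibrated()
        assert model.calibrated
        decisions = apply_model(model, [model.templates.features[0]])
        assert decisions == ["normal"]

    def test_batch_equals_one_by_one(self):
        model, _ = self._calibrated()
        gen = np.random.default_rng(11)
        queries = gen.uniform(0.01, 1, (8, 16))
        queries /= queries.sum(axis=1, keepdims=True)
        batch = apply_model(model, list(queries))
        single = [apply_model(model, [q])[0] for q in queries]
        assert batch == single

    def test_uncalibrated_model_rejected(self):
        model = DetectorModel(templates=make_templates(), metric="HD")
        with pytest.raises(ValueError, match="not calibrated"):
            apply_model(model, [np.ones(16) / 16])

    def test_json_round_trip_preserves_decisions(self, tmp_path):
        model, _ = self._calibrated()
        model.save(tmp_path / "model.json")
        loaded = DetectorModel.load(tmp_path / "model.json")
        assert loaded.metric == model.metric
        assert loaded.lam == model.lam
        assert loaded.normalization_bounds == pytest.approx(model.normalization_bounds)
        gen = np.random.default_rng(12)
        queries = gen.uniform(0.01, 1, (5, 16))
        queries /= queries.sum(axis=1, keepdims=True)
        assert apply_model(loaded, list(queries)) == apply_model(model, list(queries))

    def test_disjoint_support_is_abnormal_under_bd(self):
        # a query spectrum with no overlap with any template has BC = 0,
        # the minimum possible raw similarity, hence abnormal for lambda > 0
        templates = TemplateSet(
            features=np.array([[0.5, 0.5, 0.0, 0.0], [0.6, 0.4, 0.0, 0.0]]),
            source_ids=["t0", "t1"])
        model = DetectorModel(templates=templates, metric="BD", lam=0.5,
                              normalization_bounds=(0.0, 1.0))
        q = np.array([0.0, 0.0, 0.5, 0.5])
        assert apply_model(model, [q]) == ["abnormal"]
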