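"""Metrics, cross-validation, grid search and the trained-model contract."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from strandclass import (
    FeatureMatrix,
    ModelConfig,
    StrandclassError,
    compute_metrics,
    cross_validate,
    grid_search,
    predict,
    train_final,
)
from strandclass.model import TrainedModel, auc_score

from oracles import auc_oracle, metrics_oracle


def separable_matrix(n=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    x = rng.standard_normal((n, 3))
    x[:, 0] += y * 10.0  # wide margin
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        labels=["SSB" if v else "DSB" for v in y],
        columns=["sig", "n1", "n2"],
        values=x,
    )


class TestComputeMetrics:
    def test_perfect_prediction(self):
        truth = np.array([1, 1, 0, 0])
        rep = compute_metrics(truth, truth, truth.astype(float))
        assert (rep.sn, rep.sp, rep.accuracy, rep.f1, rep.mcc, rep.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_symmetric_confusion(self):
        truth = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 5 + [0] * 5 + [1] * 5 + [0] * 5)
        rep = compute_metrics(truth, pred, pred * 1.0)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (5, 5, 5, 5)
        assert rep.mcc == pytest.approx(0.0)
        assert rep.accuracy == pytest.approx(0.5)

    def test_hand_worked_confusion(self):
        # TP=8 FN=2 TN=9 FP=1
        truth = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 8 + [0] * 2 + [1] * 1 + [0] * 9)
        rep = compute_metrics(truth, pred, pred * 1.0)
        assert rep.sn == pytest.approx(0.8)
        assert rep.sp == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.f1 == pytest.approx(16 / 19)
        assert rep.mcc == pytest.approx(70 / math.sqrt(9 * 10 * 10 * 11))

    def test_degenerate_denominator_is_nan_not_zero(self):
        truth = np.array([0, 0, 0])
        pred = np.array([0, 0, 0])
        rep = compute_metrics(truth, pred, np.zeros(3))
        assert math.isnan(rep.sn) and math.isnan(rep.mcc) and math.isnan(rep.auc)
        assert rep.sp == 1.0

    def test_100_random_confusion_tables_match_formulas(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 20, size=4))
            if tp + tn + fp + fn == 0:
                continue
            truth = np.array([1] * (tp + fn) + [0] * (tn + fp))
            pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
            rep = compute_metrics(truth, pred, pred * 1.0)
            exp = metrics_oracle(tp, tn, fp, fn)
            for name, val in exp.items():
                got = getattr(rep, name)
                assert (math.isnan(got) and math.isnan(val)) or got == pytest.approx(val)
            # independent library cross-check where defined
            if not math.isnan(exp["mcc"]):
                assert rep.mcc == pytest.approx(matthews_corrcoef(truth, pred), abs=1e-12)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(StrandclassError, match="probabilities"):
            compute_metrics(np.array([1, 0]), np.array([1, 0]), np.array([2.0, 0.0]))


class TestAuc:
    def test_matches_all_pairs_oracle_and_sklearn(self, rng):
        truth = rng.integers(0, 2, size=50)
        truth[0], truth[1] = 1, 0
        scores = np.round(rng.uniform(0, 1, size=50), 2)  # force ties
        got = auc_score(truth, scores)
        assert got == pytest.approx(auc_oracle(truth.tolist(), scores.tolist()))
        assert got == pytest.approx(roc_auc_score(truth, scores))

    def test_invariant_to_monotone_transform(self, rng):
        truth = rng.integers(0, 2, size=40)
        truth[:2] = [0, 1]
        scores = rng.uniform(0.01, 0.99, size=40)
        assert auc_score(truth, scores) == pytest.approx(
            auc_score(truth, scores ** 3)
        )
        assert auc_score(truth, scores) == pytest.approx(
            auc_score(truth, 1 / (1 + np.exp(-5 * scores)))
        )


class TestCrossValidate:
    def test_same_seed_identical_reports(self):
        m = separable_matrix(40)
        cfg = ModelConfig(n_trees=50, seed=9)
        r1 = cross_validate(m, cfg, folds=5)
        r2 = cross_validate(m, cfg, folds=5)
        assert r1.to_dict() == r2.to_dict()

    def test_stratification_arithmetic(self):
        # 6 positives, 4 negatives, 2 folds -> 3 + 2 per fold
        rng = np.random.default_rng(0)
        y = np.array([1] * 6 + [0] * 4)
        m = FeatureMatrix(
            sample_ids=[f"s{i}" for i in range(10)],
            labels=["SSB" if v else "DSB" for v in y],
            columns=["a"],
            values=rng.standard_normal((10, 1)),
        )
        rep = cross_validate(m, ModelConfig(n_trees=10, seed=0), folds=2)
        for fold in rep.per_fold:
            assert fold.tp + fold.fn == 3  # positives per fold
            assert fold.tn + fold.fp == 2  # negatives per fold

    def test_separable_data_perfect_pooled_accuracy(self):
        rep = cross_validate(separable_matrix(40), ModelConfig(n_trees=50, seed=1), folds=5)
        assert rep.accuracy == 1.0
        assert rep.tp + rep.tn + rep.fp + rep.fn == 40

    def test_class_too_small_for_stratification(self):
        m = separable_matrix(8)
        with pytest.raises(StrandclassError, match="stratify"):
            cross_validate(m, ModelConfig(), folds=10)


class TestGridSearch:
    def test_singleton_grid_returned(self):
        m = separable_matrix(30)
        cfg = ModelConfig(seed=2, grid={"n_trees": [37]})
        best, trace = grid_search(m, cfg, folds=3)
        assert best.n_trees == 37 and len(trace) == 1

    def test_reasonable_setting_beats_degenerate(self):
        # overlapping classes: a single tiny-rate tree ranks coarsely (few
        # distinct scores), so the full ensemble wins on AUC
        rng = np.random.default_rng(5)
        n = 60
        y = np.array([1] * 30 + [0] * 30)
        x = rng.standard_normal((n, 3))
        x[:, 0] += y * 1.5
        m = FeatureMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            labels=["SSB" if v else "DSB" for v in y],
            columns=["sig", "n1", "n2"],
            values=x,
        )
        cfg = ModelConfig(
            seed=2,
            grid={"n_trees": [1, 100], "learning_rate": [1e-6, 0.1]},
        )
        best, _ = grid_search(m, cfg, folds=4)
        assert best.n_trees == 100 and best.learning_rate == 0.1

    def test_tie_breaks_to_first_grid_entry(self):
        m = separable_matrix(40, seed=3)
        # both settings reach AUC 1 on trivially separable data
        cfg = ModelConfig(seed=2, grid={"n_trees": [60, 80]})
        best, trace = grid_search(m, cfg, folds=4)
        assert trace[0][1].auc == trace[1][1].auc == 1.0
        assert best.n_trees == 60


class TestTrainPredict:
    def test_memorization_on_separable_fixture(self):
        m = separable_matrix(30)
        model = train_final(m, ModelConfig(n_trees=50, seed=0))
        scores, labels = predict(model, m)
        assert labels == m.labels
        assert np.all((scores >= 0) & (scores <= 1))

    def test_shuffled_columns_rejected(self):
        m = separable_matrix(30)
        model = train_final(m, ModelConfig(n_trees=10, seed=0))
        shuffled = m.subset_columns(["n1", "sig", "n2"])
        with pytest.raises(StrandclassError, match="reordered"):
            predict(model, shuffled)

    def test_missing_column_named(self):
        m = separable_matrix(30)
        model = train_final(m, ModelConfig(n_trees=10, seed=0))
        with pytest.raises(StrandclassError, match="sig"):
            predict(model, m.subset_columns(["n1", "n2"]))

    def test_persistence_round_trip(self, tmp_path):
        m = separable_matrix(30)
        model = train_final(m, ModelConfig(n_trees=50, seed=0))
        path = tmp_path / "model.joblib"
        model.save(path)
        reloaded = TrainedModel.load(path)
        s1, l1 = predict(model, m)
        s2, l2 = predict(reloaded, m)
        assert np.array_equal(s1, s2) and l1 == l2
        assert reloaded.config == model.config
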