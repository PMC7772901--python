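"""Metrics, the training loop, and the split + CV + hold-out protocol."""

import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, precision_recall_fscore_support)

from stresswear import (TrainConfig, build_wrist_mlp, evaluate_model,
                        map_task_labels, metrics_from_confusion, run_protocol,
                        train_model)
from stresswear.windowing import WindowSet


def _expand(confusion):
    """Confusion matrix -> (y_true, y_pred) prediction lists."""
    y_true, y_pred = [], []
    for i, row in enumerate(confusion):
        for j, count in enumerate(row):
            y_true += [i] * int(count)
            y_pred += [j] * int(count)
    return np.array(y_true), np.array(y_pred)


class TestMetricsFromConfusion:
    def test_binary_formulas_direct_substitution(self):
        # TP=4, TN=4, FP=1, FN=1 with rows=true, cols=predicted, positive=1
        rep = metrics_from_confusion([[4, 1], [1, 4]])
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_f1_is_harmonic_mean_fixed_point(self):
        # precision == recall == p implies F1 == p
        rep = metrics_from_confusion([[6, 2], [2, 6]])
        assert rep.precision == rep.recall == rep.f1 == pytest.approx(0.75)

    def test_agrees_with_prediction_list_recomputation(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            C = rng.integers(0, 12, size=(k, k))
            if C.sum() == 0:
                C[0, 0] = 1
            rep = metrics_from_confusion(C)
            y_true, y_pred = _expand(C)
            labels = list(range(k))
            assert rep.accuracy == pytest.approx(
                accuracy_score(y_true, y_pred))
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=labels, average="macro",
                zero_division=0)
            assert rep.macro["precision"] == pytest.approx(p)
            assert rep.macro["recall"] == pytest.approx(r)
            assert rep.macro["f1"] == pytest.approx(f)
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=labels, average="weighted",
                zero_division=0)
            assert rep.weighted["f1"] == pytest.approx(f)

    def test_zero_denominator_conventions(self):
        rep = metrics_from_confusion([[5, 0], [5, 0]])  # never predicts 1
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f1 == 0.0

    def test_non_square_matrix_raises(self):
        with pytest.raises(ValueError):
            metrics_from_confusion([[1, 2, 3], [4, 5, 6]])

    def test_invariants_hold(self):
        rep = metrics_from_confusion([[10, 2, 1], [0, 9, 3], [1, 1, 8]])
        assert rep.confusion.sum() == rep.n_test == 35
        for key in ("accuracy", "precision", "recall", "f1"):
            assert 0.0 <= getattr(rep, key) <= 1.0


def _mapped(ws, task):
    return map_task_labels(ws, task)


class TestTrainModel:
    def test_memorizes_a_constant_dataset(self, wrist_windows):
        ws = _mapped(wrist_windows, "binary")
        stress_idx = np.flatnonzero(ws.labels == 1)[:1]
        ws10 = ws.subset(np.repeat(stress_idx, 10))
        model = train_model(build_wrist_mlp(task="binary"), ws10,
                            TrainConfig(epochs=100, seed=0, cv_folds=0))
        assert model.history["accuracy"][-1] == 1.0

    def test_loss_decreases_on_separable_set(self, wrist_windows):
        ws = _mapped(wrist_windows, "three_class")
        model = train_model(build_wrist_mlp(task="three_class"), ws,
                            TrainConfig(epochs=10, seed=0, cv_folds=0))
        assert model.history["loss"][-1] < model.history["loss"][0]

    def test_same_seed_gives_identical_metrics(self, wrist_windows):
        ws = _mapped(wrist_windows, "three_class")
        cfg = TrainConfig(epochs=3, seed=4, cv_folds=0)
        g = build_wrist_mlp(task="three_class")
        a = train_model(g, ws, cfg)
        b = train_model(g, ws, cfg)
        assert a.history == b.history
        ra, rb = evaluate_model(a, ws), evaluate_model(b, ws)
        assert ra.to_dict() == rb.to_dict()

    def test_task_mismatch_raises(self, wrist_windows):
        ws = _mapped(wrist_windows, "binary")
        with pytest.raises(ValueError, match="task"):
            train_model(build_wrist_mlp(task="three_class"), ws,
                        TrainConfig(epochs=1))

    def test_shape_mismatch_names_the_branch(self, chest_windows):
        from stresswear import build_chest_cnn, ConvBlockSpec, ConvLayerSpec
        ws = _mapped(chest_windows, "binary")
        bad_block = ConvBlockSpec(
            (ConvLayerSpec(8, 15, 2, 4, 4), ConvLayerSpec(16, 7, 2, 4, 4),
             ConvLayerSpec(32, 3, 1, 2, 2)), input_len=7000)
        with pytest.raises(ValueError, match="ECG"):
            train_model(build_chest_cnn(bad_block, task="binary"), ws,
                        TrainConfig(epochs=1))

    def test_loss_bound_to_task(self):
        cfg = TrainConfig(loss="binary_cross_entropy")
        assert cfg.loss_for_task("binary") == "binary_cross_entropy"
        with pytest.raises(ValueError):
            cfg.loss_for_task("three_class")


class TestEvaluateModel:
    def test_perfect_predictor_scores_one(self, wrist_windows):
        ws = _mapped(wrist_windows, "three_class")
        model = train_model(build_wrist_mlp(task="three_class"), ws,
                            TrainConfig(epochs=30, seed=0, cv_folds=0))
        rep = evaluate_model(model, ws)  # training set: memorized
        if rep.accuracy == 1.0:
            assert rep.f1 == 1.0
        assert rep.n_test == len(ws)

    def test_empty_test_set_raises(self, wrist_windows):
        ws = _mapped(wrist_windows, "binary")
        model = train_model(build_wrist_mlp(task="binary"), ws,
                            TrainConfig(epochs=1, seed=0, cv_folds=0))
        with pytest.raises(ValueError):
            evaluate_model(model, ws.subset([]))

    def test_metrics_match_prediction_recount(self, wrist_windows):
        ws = _mapped(wrist_windows, "three_class")
        model = train_model(build_wrist_mlp(task="three_class"), ws,
                            TrainConfig(epochs=5, seed=1, cv_folds=0))
        rep = evaluate_model(model, ws)
        pred = model.predict(ws)
        assert rep.accuracy == pytest.approx(
            float(np.mean(pred == ws.labels)))


class TestRunProtocol:
    def test_fold_count_and_manifest(self, wrist_windows):
        ws = _mapped(wrist_windows, "three_class")
        cfg = TrainConfig(epochs=2, seed=0, cv_folds=3)
        result = run_protocol(ws, lambda t: build_wrist_mlp(task=t), cfg)
        assert len(result.fold_reports) == 3
        m = result.manifest
        assert m["n_train"] + m["n_test"] == len(ws)
        assert m["accuracy_holdout"] == result.holdout.accuracy
        assert m["accuracy_cv_mean"] == pytest.approx(
            result.cv_mean_accuracy)
        assert m["config_hash"]

    def test_fewer_windows_than_folds_raises(self, wrist_windows):
        ws = _mapped(wrist_windows, "three_class").subset(range(6))
        with pytest.raises(ValueError):
            run_protocol(ws, lambda t: build_wrist_mlp(task=t),
                         TrainConfig(epochs=1, cv_folds=10))

    def test_unmapped_dataset_raises(self, wrist_windows):
        with pytest.raises(ValueError):
            run_protocol(wrist_windows, lambda t: build_wrist_mlp(task=t),
                         TrainConfig(epochs=1))


class TestAccAblationSoftCheck:
    def test_including_acc_does_not_hurt_beyond_noise(self):
        """On the default synthetic benchmark, adding the accelerometer
        channels must not cost more than run-to-run noise."""
        from stresswear import synthetic_benchmark
        with_acc, _ = synthetic_benchmark(site="wrist", task="three_class",
                                          seed=0, include_acc=True)
        without_acc, _ = synthetic_benchmark(site="wrist", task="three_class",
                                             seed=0, include_acc=False)
        assert with_acc.accuracy >= without_acc.accuracy - 0.1
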