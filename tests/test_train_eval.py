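"""Metrics against independent oracles, and the desk-scale training loop."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

import garlicnet as gn
from garlicnet.train_eval import TrainConfig, confusion, metrics


class TestConfusion:
    def test_layout_rows_actual_columns_predicted(self):
        # binary case enumerating TP / FP / FN / TN once each
        cm = confusion(preds=[0, 0, 1, 1], truths=[0, 1, 0, 1], K=2)
        assert cm[0, 0] == 1  # actual 0 predicted 0 (TP of class 0)
        assert cm[1, 0] == 1  # actual 1 predicted 0
        assert cm[0, 1] == 1
        assert cm[1, 1] == 1

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 2, 1]
        cm = confusion(y, y, K=3)
        assert np.array_equal(cm, np.diag([1, 2, 2]))

    def test_empty_input_gives_zero_matrix(self):
        assert confusion([], [], K=3).sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0], [0, 1], K=2)


class TestMetrics:
    def test_published_f1_arithmetic(self):
        """P = 1.000 and R = 0.941 combine to F1 = 0.970 (harmonic mean)."""
        cm = np.array([[16, 1, 0],
                       [0, 17, 0],
                       [0, 0, 17]])
        rep = metrics(cm)
        assert rep.per_class[0]["P"] == pytest.approx(1.000, abs=5e-4)
        assert rep.per_class[0]["R"] == pytest.approx(0.941, abs=5e-4)
        assert rep.per_class[0]["F1"] == pytest.approx(0.970, abs=5e-4)

    def test_perfect_matrix(self):
        rep = metrics(np.diag([5, 5, 5]))
        assert rep.acc == rep.macro_P == rep.macro_R == rep.macro_F1 == 1.0

    def test_symmetric_binary_case(self):
        rep = metrics(np.array([[1, 1], [1, 1]]))
        assert rep.acc == 0.5
        for k in (0, 1):
            assert rep.per_class[k] == {"P": 0.5, "R": 0.5, "F1": 0.5}

    def test_zero_predicted_positives_warns_and_defines_zero(self):
        cm = np.array([[0, 3], [0, 5]])  # class 0 never predicted
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = metrics(cm)
        assert rep.per_class[0]["P"] == 0.0

    def test_matches_sklearn_on_500_random_matrices(self):
        """Per-class and macro P/R/F1 agree with the independent
        per-definition computation for 500 random label sets."""
        import warnings

        rng = np.random.default_rng(99)
        for _ in range(500):
            K = int(rng.integers(2, 6))
            n = int(rng.integers(K, 60))
            truths = rng.integers(0, K, size=n)
            preds = rng.integers(0, K, size=n)
            cm = confusion(preds, truths, K)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-division convention
                rep = metrics(cm)
            p, r, f1, _ = precision_recall_fscore_support(
                truths, preds, labels=range(K), zero_division=0)
            for k in range(K):
                assert rep.per_class[k]["P"] == pytest.approx(p[k])
                assert rep.per_class[k]["R"] == pytest.approx(r[k])
                assert rep.per_class[k]["F1"] == pytest.approx(f1[k])
            assert rep.macro_F1 == pytest.approx(f1.mean())
            assert rep.acc == pytest.approx((preds == truths).mean())

    def test_macro_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        truths = rng.integers(0, 3, size=120)
        preds = rng.integers(0, 3, size=120)
        base = metrics(confusion(preds, truths, 3)).macro_F1
        perm = np.array([2, 0, 1])
        permuted = metrics(confusion(perm[preds], perm[truths], 3)).macro_F1
        assert permuted == pytest.approx(base)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.zeros((3, 3)))


class TestTrainingLoop:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        ds, _ = gn.generate_dataset(4, image_size=64, seed=1)
        net = gn.build_model("dh_garlicnet", 3, seed=0,
                             stage_channels=(4, 8, 16, 32))
        before = {k: v.copy() for k, v in net.state_dict().items()
                  if not k.endswith(("running_mean", "running_var"))}
        cfg = TrainConfig(input_size=64, batch_size=8, lr=0.0, epochs=1,
                          seed=0)
        net, _ = gn.train(net, ds, ds, cfg)
        after = net.state_dict()
        for k, v in before.items():
            assert np.array_equal(v, after[k]), k

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)

    def test_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert (cfg.input_size, cfg.batch_size, cfg.lr, cfg.epochs) == (
            224, 8, 0.01, 30)

    def test_history_and_convergence(self, smoke_run):
        """History has one entry per epoch and the loss decreases overall."""
        hist = smoke_run["history"]
        epochs = smoke_run["config"].epochs
        assert len(hist.train_loss) == epochs
        assert len(hist.val_loss) == epochs
        assert len(hist.val_acc) == epochs
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_smoke_training_reaches_high_validation_accuracy(self, smoke_run):
        """Desk-scale full classifier separates the three synthetic classes:
        best validation accuracy at least 0.95 within five epochs."""
        assert max(smoke_run["history"].val_acc) >= 0.95

    def test_returned_network_holds_best_checkpoint(self, smoke_run):
        net = smoke_run["net"]
        ds = smoke_run["dataset"]
        plan = smoke_run["plan"]
        cm, rep = gn.evaluate(net, ds.subset(plan.val_idx), input_size=64)
        best = max(smoke_run["history"].val_acc)
        assert rep.acc == pytest.approx(best)


class TestEvaluate:
    def test_constant_predictor_on_balanced_set(self):
        ds, _ = gn.generate_dataset(4, image_size=64, seed=3)
        net = gn.build_model("resnet34", 3, stage_channels=(4, 8, 16, 32))
        net.fc.weight.data[...] = 0.0
        net.fc.bias.data[...] = np.array([1.0, 0.0, 0.0])
        cm, rep = gn.evaluate(net, ds, input_size=64)
        assert rep.acc == pytest.approx(1.0 / 3.0)
        assert cm[:, 0].sum() == len(ds)

    def test_evaluation_is_bit_identical(self, smoke_run):
        net = smoke_run["net"]
        ds = smoke_run["dataset"].subset(smoke_run["plan"].test_idx)
        cm1, rep1 = gn.evaluate(net, ds, input_size=64)
        cm2, rep2 = gn.evaluate(net, ds, input_size=64)
        assert np.array_equal(cm1, cm2)
        assert rep1.loss == rep2.loss

    def test_metrics_are_finite_and_bounded(self, smoke_run):
        ds = smoke_run["dataset"].subset(smoke_run["plan"].test_idx)
        _, rep = gn.evaluate(smoke_run["net"], ds, input_size=64)
        for v in (rep.acc, rep.macro_P, rep.macro_R, rep.macro_F1):
            assert 0.0 <= v <= 1.0
        assert np.isfinite(rep.loss)

    def test_empty_set_rejected(self, smoke_run):
        empty = gn.Dataset([], ["local_damage", "root_damage", "normal"])
        with pytest.raises(ValueError):
            gn.evaluate(smoke_run["net"], empty)
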