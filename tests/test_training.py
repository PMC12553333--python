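"""Losses (closed forms + gradients), the training loop, and prediction."""

import numpy as np
import pytest

from protbench import TaskSpec, TrainConfig, make_split
from protbench.errors import NonFiniteLoss
from protbench.nn.tensor import Tensor
from protbench.synthetic import GeneratorSpec, generate
from protbench.training import (
    binary_cross_entropy_loss,
    cross_entropy_loss,
    loss_for_task,
    mse_loss,
    predict,
    residue_cross_entropy_loss,
    train,
)
from protbench.zoo import build_model
from protbench.zoo.batches import ModelBatch


class TestLossSelection:
    @pytest.mark.parametrize("task_kw,expected", [
        (dict(arity="single", objective="regression"), "mse"),
        (dict(arity="pair", objective="regression"), "mse"),
        (dict(arity="single", objective="binary"), "cross_entropy"),
        (dict(arity="single", objective="multiclass", num_classes=4),
         "cross_entropy"),
        (dict(arity="pair", objective="binary"), "binary_cross_entropy"),
        (dict(arity="single", level="residue", objective="binary"),
         "residue_cross_entropy"),
    ])
    def test_loss_is_function_of_task(self, task_kw, expected):
        ts = TaskSpec(name="t", **task_kw)
        assert loss_for_task(ts).kind == expected


class TestClosedForms:
    def test_mse_zero_at_truth(self):
        pred = Tensor(np.array([1.0, -2.0, 3.0]))
        assert mse_loss(pred, np.array([1.0, -2.0, 3.0])).data == 0.0

    def test_bce_at_half_is_ln2(self):
        # sigmoid(0) = 0.5, so BCE(0.5, 1) = ln 2
        loss = binary_cross_entropy_loss(Tensor(np.zeros(1)), np.array([1.0]))
        np.testing.assert_allclose(loss.data, np.log(2.0), rtol=1e-12)

    def test_uniform_three_class_ce_is_ln3(self):
        logits = Tensor(np.zeros((4, 3)))
        loss = cross_entropy_loss(logits, np.array([0, 1, 2, 0]))
        np.testing.assert_allclose(loss.data, np.log(3.0), rtol=1e-12)

    def test_residue_ce_uniform_is_ln3_per_token(self):
        logits = Tensor(np.zeros((2, 5, 3)))
        target = np.zeros((2, 5), dtype=int)
        mask = np.array([[1, 1, 1, 0, 0], [1, 1, 1, 1, 1]], dtype=float)
        loss = residue_cross_entropy_loss(logits, target, mask)
        np.testing.assert_allclose(loss.data, np.log(3.0), rtol=1e-12)

    def test_losses_nonnegative(self):
        rng = np.random.default_rng(0)
        z = Tensor(rng.standard_normal(8))
        y = rng.integers(0, 2, 8).astype(float)
        assert binary_cross_entropy_loss(z, y).data >= 0
        assert mse_loss(z, rng.standard_normal(8)).data >= 0


class TestLossGradients:
    """Finite-difference check of each loss through a 3-parameter toy model."""

    @staticmethod
    def _check(loss_fn, n_out, target, **kw):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 3))
        w = Tensor(rng.standard_normal(3), requires_grad=True)

        def fwd():
            z = Tensor(X, requires_grad=False) @ w.reshape(3, 1)
            z = z.reshape(*((4,) if n_out == 1 else (4 // n_out, n_out)))
            return loss_fn(z, target, **kw)

        loss = fwd()
        loss.backward()
        analytic = w.grad.copy()
        eps = 1e-6
        for i in range(3):
            w.data[i] += eps
            lp = float(fwd().data)
            w.data[i] -= 2 * eps
            lm = float(fwd().data)
            w.data[i] += eps
            num = (lp - lm) / (2 * eps)
            rel = abs(num - analytic[i]) / max(1e-8, abs(num) + abs(analytic[i]))
            assert rel < 1e-4

    def test_mse_gradient(self):
        self._check(mse_loss, 1, np.array([0.3, -1.0, 0.5, 2.0]))

    def test_bce_gradient(self):
        self._check(binary_cross_entropy_loss, 1, np.array([1.0, 0.0, 1.0, 0.0]))

    def test_ce_gradient(self):
        self._check(cross_entropy_loss, 2, np.array([0, 1]))

    def test_residue_ce_gradient(self):
        mask = np.array([[1.0, 1.0]])
        self._check(
            lambda z, t: residue_cross_entropy_loss(
                z.reshape(1, 2, 2), t, mask), 2,
            np.array([[0, 1]]))


def _regression_setup(n=40, seed=0, noise=0.0):
    ts = TaskSpec(name="reg", objective="regression")
    recs = generate(GeneratorSpec(task_spec=ts, n_samples=n,
                                  length_range=(10, 16), motifs=("WKW",),
                                  noise=noise, seed=seed))
    return ts, make_split(recs, seed=seed)


class TestTrainLoop:
    def test_zero_epochs_leaves_parameters_untouched(self):
        ts, split = _regression_setup()
        model = build_model("cnn", ts, seed=0)
        before = model.state_dict()
        model, hist = train(model, split, ts,
                            TrainConfig(max_epochs=0, seed=0))
        assert len(hist) == 0
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_zero_learning_rate_keeps_loss_constant(self):
        ts, split = _regression_setup()
        model = build_model("cnn", ts, seed=0)
        _, hist = train(model, split, ts,
                        TrainConfig(learning_rate=0.0, max_epochs=3, seed=0,
                                    dropout=0.0))
        assert np.allclose(hist.train_loss, hist.train_loss[0])

    def test_seed_determinism(self):
        ts, split = _regression_setup()
        runs = []
        for _ in range(2):
            model = build_model("cnn", ts, seed=0)
            model, hist = train(model, split, ts,
                                TrainConfig(learning_rate=1e-3, max_epochs=3,
                                            seed=11))
            runs.append((hist.train_loss, model.state_dict()))
        assert runs[0][0] == runs[1][0]
        for k in runs[0][1]:
            np.testing.assert_array_equal(runs[0][1][k], runs[1][1][k])

    def test_different_seed_changes_trajectory(self):
        ts, split = _regression_setup()
        losses = []
        for seed in (1, 2):
            model = build_model("cnn", ts, seed=seed)
            _, hist = train(model, split, ts,
                            TrainConfig(learning_rate=1e-3, max_epochs=2,
                                        seed=seed))
            losses.append(hist.train_loss)
        assert losses[0] != losses[1]

    def test_noise_free_regression_loss_decreases_after_warmup(self):
        ts, split = _regression_setup(n=160, noise=0.0)
        model = build_model("cnn", ts, seed=0)
        _, hist = train(model, split, ts,
                        TrainConfig(learning_rate=1e-4, max_epochs=8, seed=0))
        tail = hist.train_loss[3:]
        assert all(b <= a + 1e-6 for a, b in zip(tail, tail[1:]))

    def test_non_finite_loss_aborts_with_diagnostic(self):
        ts, split = _regression_setup(n=20)
        split.train[0].label = float("inf")
        model = build_model("cnn", ts, seed=0)
        with pytest.raises(NonFiniteLoss):
            train(model, split, ts, TrainConfig(max_epochs=1, seed=0))

    def test_early_stopping_restores_best_epoch(self):
        ts, split = _regression_setup(n=80, noise=0.0)
        model = build_model("cnn", ts, seed=0)
        _, hist = train(model, split, ts,
                        TrainConfig(learning_rate=1e-3, max_epochs=30, seed=0,
                                    early_stop_patience=2))
        assert len(hist) <= 30


class TestPredict:
    def test_regression_table_one_row_per_record(self):
        ts, split = _regression_setup(n=20)
        model = build_model("cnn", ts, seed=0)
        table = predict(model, split.test[:5], ts)
        assert len(table) == len(split.test[:5])
        assert {"id", "score", "pred"} <= set(table.columns)

    def test_residue_rows_keyed_by_id_and_position(self, residue_task):
        recs = generate(GeneratorSpec(task_spec=residue_task, n_samples=2,
                                      length_range=(9, 9), motifs=("WWW",),
                                      seed=0))
        model = build_model("cnn", residue_task, seed=0)
        table = predict(model, recs[:1], residue_task)
        assert len(table) == 9
        assert table["position"].tolist() == list(range(9))

    def test_predict_is_deterministic(self, binary_task):
        recs = generate(GeneratorSpec(task_spec=binary_task, n_samples=6,
                                      length_range=(10, 14),
                                      motifs=("WKW", "CHC"), seed=0))
        model = build_model("cnn", binary_task, seed=0)
        t1 = predict(model, recs, binary_task)
        t2 = predict(model, recs, binary_task)
        assert t1.equals(t2)

    def test_task_mismatch_rejected(self, binary_task, regression_task):
        model = build_model("cnn", binary_task, seed=0)
        with pytest.raises(Exception):
            predict(model, [], regression_task)
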