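"""Convolutional head shapes, losses, and frozen-encoder training."""

import numpy as np
import pytest

from molsent import (
    GeneratorSpec,
    PlantedTask,
    PredictorConfig,
    auc,
    gen_molecules,
    plant_property,
    random_split,
    rmse,
    train_predictor,
)
from molsent.nn import Tensor
from molsent.predictor import (
    ConvHead,
    classification_loss,
    conv_features,
    global_max_pool,
    predict,
    regression_loss,
)


def make_head(task="classification", k=5, c=8, H=16, fc=4, seed=0):
    cfg = PredictorConfig(task=task, kernel_length=k, n_kernels=c, fc_units=fc)
    return ConvHead(cfg, H, seed=seed)


class TestConvFeatures:
    def test_output_shape_valid_convolution(self, rng):
        head = make_head(k=5, c=512, H=16)
        x = rng.standard_normal((11, 16)).astype(np.float32)
        assert conv_features(x, head).shape == (7, 512)

    def test_zero_input_zero_bias_gives_zeros(self):
        head = make_head(k=3, c=6, H=8)
        out = conv_features(np.zeros((10, 8), dtype=np.float32), head)
        np.testing.assert_array_equal(out, np.zeros((8, 6)))

    def test_pointwise_kernel_preserves_length(self, rng):
        head = make_head(task="regression", k=1, c=4, H=8)
        x = rng.standard_normal((9, 8)).astype(np.float32)
        assert conv_features(x, head).shape == (9, 4)

    def test_too_short_input_instructs_padding(self, rng):
        head = make_head(k=5, c=4, H=8)
        with pytest.raises(ValueError, match="pad"):
            conv_features(rng.standard_normal((3, 8)).astype(np.float32), head)

    @pytest.mark.parametrize("n,k,c", [(5, 1, 3), (5, 5, 1), (12, 4, 7), (30, 5, 16)])
    def test_shape_contract_sweep(self, n, k, c, rng):
        head = make_head(k=k, c=c, H=8)
        x = rng.standard_normal((n, 8)).astype(np.float32)
        assert conv_features(x, head).shape == (n - k + 1, c)

    def test_matches_scalar_loop_convolution(self, rng):
        """Cross-check the sliced-matmul convolution against an explicit
        position-by-position loop."""
        head = make_head(k=3, c=4, H=5)
        x = rng.standard_normal((8, 5)).astype(np.float32)
        out = conv_features(x, head)
        w = head.conv_weight.data  # (k, H, C)
        for pos in range(6):
            expect = head.conv_bias.data.copy()
            for j in range(3):
                expect = expect + x[pos + j] @ w[j]
            np.testing.assert_allclose(out[pos], np.maximum(expect, 0), atol=1e-5)


class TestGlobalMaxPool:
    def test_single_position_identity(self, rng):
        row = rng.standard_normal((1, 6))
        np.testing.assert_array_equal(global_max_pool(row), row[0])

    def test_pad_exclusion(self, rng):
        o = rng.standard_normal((4, 6))
        padded = np.vstack([o, 100 * np.ones((2, 6))])
        valid = np.array([True] * 4 + [False] * 2)
        np.testing.assert_array_equal(
            global_max_pool(padded, valid), global_max_pool(o)
        )

    def test_max_definition(self):
        col = np.array([[1.0], [-2.0], [3.0]])
        assert global_max_pool(col)[0] == 3.0

    def test_zero_valid_positions_error(self):
        with pytest.raises(ValueError):
            global_max_pool(np.ones((3, 2)), np.zeros(3, dtype=bool))

    def test_pooling_pad_invariance_across_random_models(self, rng):
        for seed in range(20):
            head = make_head(k=2, c=4, H=6, seed=seed)
            x = rng.standard_normal((7, 6)).astype(np.float32)
            base = head.forward_states(Tensor(x[None]), np.array([7])).data
            padded = np.vstack([x, np.zeros((3, 6), dtype=np.float32)])
            same = head.forward_states(Tensor(padded[None]), np.array([7])).data
            np.testing.assert_allclose(base, same, atol=1e-6)


class TestPredict:
    def test_classification_output_in_unit_interval(self, rng):
        head = make_head(task="classification", c=4, fc=3)
        for _ in range(20):
            y = predict(rng.standard_normal(4) * 10, head)
            assert 0.0 < y < 1.0

    def test_zero_weights_regression_gives_zero(self):
        head = make_head(task="regression", c=4, fc=3)
        head.fc.weight.data[:] = 0
        head.fc.bias.data[:] = 0
        head.out.weight.data[:] = 0
        head.out.bias.data[:] = 0
        assert predict(np.ones(4), head) == 0.0

    def test_regression_can_emit_negative_values(self):
        head = make_head(task="regression", c=2, fc=2)
        head.fc.weight.data[:] = 0
        head.fc.bias.data[:] = [1.0, 0.0]
        head.out.weight.data[:] = 0
        head.out.bias.data[:] = -1.0
        assert predict(np.zeros(2), head) == -1.0


class TestLosses:
    def test_confident_correct_classification_loss_vanishes(self):
        assert classification_loss([1 - 1e-9], [1]) < 1e-6

    def test_maximum_uncertainty_gives_log_two(self):
        assert classification_loss([0.5, 0.5], [0, 1]) == pytest.approx(np.log(2))

    def test_label_flip_symmetry(self, rng):
        y = rng.uniform(0.01, 0.99, size=20)
        t = rng.integers(0, 2, size=20)
        assert classification_loss(y, t) == pytest.approx(
            classification_loss(1 - y, 1 - t)
        )

    def test_out_of_range_prediction_errors(self):
        with pytest.raises(ValueError):
            classification_loss([1.2], [1])

    def test_regression_loss_closed_forms(self):
        assert regression_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert regression_loss([2.0, 0.0], [1.0, 1.0]) == 1.0

    def test_regression_loss_homogeneity(self, rng):
        t = rng.standard_normal(30)
        r = rng.standard_normal(30)
        base = regression_loss(t + r, t)
        assert regression_loss(t + 3 * r, t) == pytest.approx(9 * base)

    def test_losses_match_scalar_loop_oracles(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            y = rng.uniform(1e-6, 1 - 1e-6, size=n)
            t = rng.integers(0, 2, size=n).astype(float)
            loop = -sum(
                ti * np.log(yi) + (1 - ti) * np.log(1 - yi) for yi, ti in zip(y, t)
            ) / n
            assert classification_loss(y, t) == pytest.approx(loop, abs=1e-10)
            yr = rng.standard_normal(n)
            tr = rng.standard_normal(n)
            loop_mse = sum((a - b) ** 2 for a, b in zip(yr, tr)) / n
            assert regression_loss(yr, tr) == pytest.approx(loop_mse, abs=1e-10)

    def test_rmse_squared_equals_regression_loss(self, rng):
        y, t = rng.standard_normal(25), rng.standard_normal(25)
        assert rmse(y, t) ** 2 == pytest.approx(regression_loss(y, t))


class TestTrainPredictor:
    def _data(self, task, noise, seed):
        mols = gen_molecules(GeneratorSpec(n_molecules=600, seed=21))
        rows = plant_property(mols, PlantedTask(task=task, noise=noise), seed=seed)
        y = np.array([r[1] for r in rows])
        split = random_split(len(mols), seed=1)
        tr = ([mols[i] for i in split.train], y[split.train])
        va = ([mols[i] for i in split.validation], y[split.validation])
        te = ([mols[i] for i in split.test], y[split.test])
        return tr, va, te

    def test_encoder_frozen_and_noiseless_task_recovered(self, tiny_encoder, tiny_vocab):
        """A noiseless planted-motif task is linearly separable from the
        substructure states; held-out AUC must exceed 0.95 and the encoder
        must be bit-identical afterwards."""
        model, _ = tiny_encoder
        tr, va, te = self._data("classification", 0.0, 3)
        checksum = model.checksum()
        cfg = PredictorConfig(
            task="classification", n_kernels=64, fc_units=32, max_epochs=30, patience=8
        )
        pm, log = train_predictor(tr, va, model, tiny_vocab, cfg, seed=5)
        assert model.checksum() == checksum
        assert max(r["val_metric"] for r in log) > 0.95
        preds = pm.predict_smiles(te[0])
        assert auc(preds, te[1]) >= 0.95

    def test_seeded_determinism(self, tiny_encoder, tiny_vocab):
        model, _ = tiny_encoder
        tr, va, _ = self._data("classification", 0.0, 3)
        cfg = PredictorConfig(
            task="classification", n_kernels=16, fc_units=8, max_epochs=2
        )
        _, log_a = train_predictor(tr, va, model, tiny_vocab, cfg, seed=9)
        _, log_b = train_predictor(tr, va, model, tiny_vocab, cfg, seed=9)
        assert log_a == log_b

    def test_planted_regression_learns_signal(self, tiny_encoder, tiny_vocab):
        """Regression on y = motif count + noise at smoke-test scale: the
        head must clearly beat the constant-mean predictor on held-out data
        (the full-scale recovery bound is exercised in the acceptance suite)."""
        model, _ = tiny_encoder
        tr, va, te = self._data("regression", 0.1, 4)
        cfg = PredictorConfig(
            task="regression", n_kernels=128, fc_units=64, max_epochs=40, patience=8
        )
        pm, _ = train_predictor(tr, va, model, tiny_vocab, cfg, seed=6)
        preds = pm.predict_smiles(te[0])
        baseline = float(np.std(te[1]))
        assert rmse(preds, te[1]) < 0.6 * baseline

    def test_mismatched_labels_rejected(self, tiny_encoder, tiny_vocab):
        model, _ = tiny_encoder
        with pytest.raises(ValueError, match="binary"):
            train_predictor(
                (["CCO", "CCC"], np.array([0.3, 1.7])),
                (["CCN"], np.array([1.0])),
                model,
                tiny_vocab,
                PredictorConfig(task="classification", n_kernels=4),
                seed=0,
            )
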