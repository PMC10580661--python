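"""Network correctness: gradients, determinism, parameter counts, training."""

import numpy as np
import pytest

from kdeep.model import (
    KDeepModel,
    ModelConfig,
    _backward,
    _bce,
    _forward,
    attention_scores,
    build_model,
    count_trainable_parameters,
    load_model,
    parameter_breakdown,
    predict,
    save_model,
    train,
)
from kdeep.encode import encode_batch
from kdeep.simulate import SyntheticSpec, make_dataset

TINY = dict(
    n_filters=3, filter_width=3, pool_size=2, lstm_units=4, dense_units=5,
    input_cols=4, dropout_cnn=0.0, dropout_lstm=0.0,
)


def tiny_inputs(rng, B=3, S=11, C=4):
    X = rng.random((B, S, C))
    mask = np.ones((B, S), dtype=bool)
    mask[1, 8:] = False  # one variable-length strand
    return X, mask


class TestBuild:
    def test_same_seed_identical_parameters(self):
        a = build_model(ModelConfig(seed=11))
        b = build_model(ModelConfig(seed=11))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_different_seed_different_parameters(self):
        a = build_model(ModelConfig(seed=1))
        b = build_model(ModelConfig(seed=2))
        assert any((a.params[k] != b.params[k]).any() for k in a.params)

    def test_dna_config_filter_count(self):
        cfg = ModelConfig.dna()
        assert cfg.n_filters == 320 and cfg.n_outputs == 919

    def test_untrained_outputs_in_unit_interval(self, rng):
        model = build_model(ModelConfig(**TINY, n_outputs=3, seed=0))
        X, mask = tiny_inputs(rng)
        y = predict(model, X, mask)
        assert y.shape == (3, 3) and ((y > 0) & (y < 1)).all()

    def test_first_layer_filters_shape(self):
        model = build_model(ModelConfig(**TINY, seed=0))
        assert model.first_layer_filters.shape == (3, 3, 4)


class TestParameterCount:
    @staticmethod
    def closed_form(cfg: ModelConfig) -> int:
        F, C, K, H, D = (cfg.filter_width, cfg.input_cols, cfg.n_filters,
                         cfg.lstm_units, cfg.dense_units)
        n = F * C * K + K  # conv
        if cfg.use_attention:
            n += K * K + K + K
        n += 2 * (K * 4 * H + H * 4 * H + 4 * H)  # both LSTM directions
        n += 2 * H * D + D + D * cfg.n_outputs + cfg.n_outputs
        return n

    def test_conv_layer_arithmetic(self):
        model = build_model(ModelConfig(n_filters=4, filter_width=3, input_cols=16))
        sizes = parameter_breakdown(model)
        assert sizes["Wc"] + sizes["bc"] == 4 * (3 * 16) + 4 == 196

    @pytest.mark.parametrize("cols", [16, 64])
    @pytest.mark.parametrize("attention", [False, True])
    def test_total_matches_closed_form(self, cols, attention):
        cfg = ModelConfig(**{**TINY, "input_cols": cols}, use_attention=attention)
        assert count_trainable_parameters(build_model(cfg)) == self.closed_form(cfg)

    def test_count_seed_invariant(self):
        a = build_model(ModelConfig(seed=1))
        b = build_model(ModelConfig(seed=99))
        assert count_trainable_parameters(a) == count_trainable_parameters(b)


class TestGradients:
    @pytest.mark.parametrize("attention", [False, True])
    def test_analytic_matches_numerical(self, attention):
        cfg = ModelConfig(**TINY, n_outputs=2, use_attention=attention, seed=3)
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        X, mask = tiny_inputs(rng)
        labels = rng.integers(0, 2, (3, 2)).astype(float)
        y, cache = _forward(model.params, cfg, X, mask)
        grads = _backward(model.params, cfg, cache, (y - labels) / y.size)

        def loss():
            yy, _ = _forward(model.params, cfg, X, mask)
            return _bce(yy, labels)

        eps = 1e-6
        pick = np.random.default_rng(1)
        for name, p in model.params.items():
            flat_idx = pick.choice(p.size, size=min(5, p.size), replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp = loss()
                p[ix] = orig - eps
                lm = loss()
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name][ix]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-9), name


class TestAttention:
    def test_scores_normalize_per_strand(self, rng):
        model = build_model(ModelConfig(**TINY, use_attention=True, seed=0))
        X, mask = tiny_inputs(rng)
        alpha = attention_scores(model, X, mask)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        assert (alpha >= 0).all()

    def test_identical_strands_identical_scores(self, rng):
        model = build_model(ModelConfig(**TINY, use_attention=True, seed=0))
        X, mask = tiny_inputs(rng)
        X[1], mask[1] = X[0], mask[0]
        alpha = attention_scores(model, X, mask)
        np.testing.assert_array_equal(alpha[0], alpha[1])

    def test_model_without_attention_errors(self, rng):
        model = build_model(ModelConfig(**TINY, seed=0))
        X, mask = tiny_inputs(rng)
        with pytest.raises(ValueError, match="without attention"):
            attention_scores(model, X, mask)


class TestPredict:
    def test_repeated_calls_identical(self, rng):
        model = build_model(ModelConfig(**TINY, seed=0))
        X, mask = tiny_inputs(rng)
        np.testing.assert_array_equal(predict(model, X, mask), predict(model, X, mask))

    def test_batch_invariance(self, rng):
        model = build_model(ModelConfig(**TINY, seed=0))
        X, mask = tiny_inputs(rng, B=5)
        full = predict(model, X, mask)
        one = predict(model, X[2:3], mask[2:3])
        np.testing.assert_allclose(one[0], full[2], atol=1e-10)

    def test_shape_mismatch_errors(self, rng):
        model = build_model(ModelConfig(**TINY, seed=0))
        X, mask = tiny_inputs(rng)
        with pytest.raises(ValueError):
            predict(model, X, mask[:, :-1])

    def test_filter_wider_than_input_errors(self, rng):
        model = build_model(ModelConfig(**{**TINY, "filter_width": 20}, seed=0))
        X, mask = tiny_inputs(rng)
        with pytest.raises(ValueError, match="filter width"):
            predict(model, X, mask)


def small_training_problem(seed=0, n=120):
    spec = SyntheticSpec(n_pos=n // 2, n_neg=n // 2, length=40, seed=seed)
    ds, _ = make_dataset(spec)
    X, mask, y = encode_batch(ds, "2lk", 3, 2)
    return X, mask, y


class TestTrain:
    def test_loss_decreases_on_learnable_problem(self):
        X, mask, y = small_training_problem()
        model = build_model(ModelConfig(n_filters=8, filter_width=8, pool_size=4,
                                        lstm_units=8, dense_units=16, seed=0))
        train(model, X, mask, y, epochs=5, batch_size=16, learning_rate=0.01)
        log = model.training_log
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_all_zero_labels_converges_to_zero(self):
        X, mask, _ = small_training_problem()
        y = np.zeros((X.shape[0], 1))
        model = build_model(ModelConfig(n_filters=4, filter_width=8, pool_size=4,
                                        lstm_units=4, dense_units=8, seed=0))
        train(model, X, mask, y, epochs=30, batch_size=16, learning_rate=0.01,
              validation_fraction=0.0)
        preds = predict(model, X, mask)
        assert _bce(preds, y) < 0.1

    def test_same_seed_same_training_log(self):
        X, mask, y = small_training_problem()
        logs = []
        for _ in range(2):
            model = build_model(ModelConfig(n_filters=4, filter_width=8, pool_size=4,
                                            lstm_units=4, dense_units=8, seed=3))
            train(model, X, mask, y, epochs=3, batch_size=16)
            logs.append([e["train_loss"] for e in model.training_log])
        assert logs[0] == logs[1]

    def test_shape_mismatch_rejected_before_training(self, rng):
        model = build_model(ModelConfig(**TINY, seed=0))
        X, mask = tiny_inputs(rng)
        with pytest.raises(ValueError, match="labels"):
            train(model, X, mask, np.zeros((7, 1)))


class TestSaveLoad:
    def test_round_trip_bitwise_predictions(self, rng, tmp_path):
        model = build_model(ModelConfig(**TINY, use_attention=True, seed=0))
        model.training_log = [dict(epoch=0, train_loss=0.5)]
        X, mask = tiny_inputs(rng)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(predict(model, X, mask), predict(back, X, mask))
        assert back.config == model.config
        assert back.training_log == model.training_log

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope")
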