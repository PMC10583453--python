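import numpy as np
import pytest

from gliocam import nn
from gliocam.preprocessing import SurvivalLabel
from gliocam.survival_model import (ModelConfig, TrainConfig, build_model,
                                    load_model, predict_scores, save_model,
                                    train)

CFG = ModelConfig(input_shape=(16, 16, 8))


def separable_cohort(n_per_class=4, shape=(16, 16, 8), seed=0):
    """Volume-coded classes: cube side grows with class index."""
    rng = np.random.default_rng(seed)
    cohort = []
    for label in SurvivalLabel:
        side = 2 + 3 * label.value
        for _ in range(n_per_class):
            vol = np.zeros(shape + (4,), dtype=np.float32)
            x0 = rng.integers(1, shape[0] - side - 1)
            y0 = rng.integers(1, shape[1] - side - 1)
            z0 = rng.integers(0, max(shape[2] - side, 1))
            vol[x0:x0 + side, y0:y0 + side, z0:z0 + side, :] = (
                1.0 + 0.1 * rng.standard_normal((side, side, side, 4)))
            cohort.append((vol, label))
    return cohort


class TestBuildModel:
    def test_output_probability_vector(self, rng):
        model = build_model(CFG, seed=0)
        scores = predict_scores(model, rng.random((16, 16, 8, 4)))
        assert scores.probabilities.shape == (3,)
        assert scores.probabilities.sum() == pytest.approx(1.0)
        assert (scores.probabilities >= 0).all()

    def test_parameter_count_closed_form(self):
        model = build_model(CFG, seed=0)
        k3 = 27
        expected = 0
        in_ch = 4
        for f in (6, 16, 32):
            expected += k3 * in_ch * f + f  # conv weights + bias
            expected += 2 * f               # batch-norm gamma + beta
            in_ch = f
        flat = 2 * 2 * 1 * 32  # (16,16,8) after three 2x poolings, 32 maps
        expected += flat * 3 + 3
        assert model.n_params == expected

    def test_zeroed_final_layer_gives_uniform_probabilities(self, rng):
        model = build_model(CFG, seed=0)
        dense = model.layers[-1]
        dense.W[...] = 0
        dense.b[...] = 0
        scores = predict_scores(model, rng.random((16, 16, 8, 4)))
        np.testing.assert_allclose(scores.probabilities, np.full(3, 1 / 3),
                                   atol=1e-7)

    def test_predicted_class_is_argmax_logit(self):
        from gliocam.survival_model import PredictionScores
        for logits in ([3.0, 1.0, 2.0], [0.0, 5.0, -1.0], [-2.0, -3.0, -1.0]):
            s = PredictionScores(logits=np.array(logits),
                                 probabilities=nn.softmax(np.array(logits)))
            assert s.predicted_class.value == int(np.argmax(logits))

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="small"):
            build_model(ModelConfig(input_shape=(4, 4, 4)))

    @pytest.mark.parametrize("filters", [(16, 6, 32), (6, 6, 32)])
    def test_filters_must_increase(self, filters):
        with pytest.raises(ValueError, match="increasing"):
            ModelConfig(filters_per_block=filters)


class TestGradients:
    def test_cam_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(input_shape=(8, 8, 8), in_channels=2,
                          filters_per_block=(1, 2, 3), dropout=0.0)
        model = build_model(cfg, seed=1, dtype=np.float64)
        x = rng.random((8, 8, 8, 2))
        acts, grads, _ = model.class_score_gradients(x, 1)
        eps = 1e-5
        for _ in range(25):
            idx = tuple(rng.integers(0, s) for s in acts.shape)
            up, down = acts.copy(), acts.copy()
            up[idx] += eps
            down[idx] -= eps
            fd = (model.head_forward(up)[0, 1]
                  - model.head_forward(down)[0, 1]) / (2 * eps)
            assert grads[idx] == pytest.approx(fd, rel=1e-3, abs=1e-9)

    def test_inference_is_deterministic_despite_dropout(self, rng):
        model = build_model(CFG, seed=0)
        x = rng.random((16, 16, 8, 4))
        a = predict_scores(model, x)
        b = predict_scores(model, x)
        np.testing.assert_array_equal(a.logits, b.logits)


class TestTraining:
    def test_loss_decreases(self):
        cohort = separable_cohort()
        model = build_model(CFG, seed=1)
        cfg = TrainConfig(max_epochs=30, learning_rate=0.01, seed=2,
                          augment=False)
        result = train(model, cohort, cfg)
        assert result.loss_history[-1] < result.loss_history[0]

    def test_separable_cohort_reaches_high_accuracy(self):
        cohort = separable_cohort()
        model = build_model(CFG, seed=1)
        result = train(model, cohort, TrainConfig(max_epochs=30,
                                                  learning_rate=0.01, seed=2,
                                                  augment=False))
        preds = [predict_scores(model, vol).predicted_class
                 for vol, _ in cohort]
        acc = np.mean([p == lab for p, (_, lab) in zip(preds, cohort)])
        assert acc >= 0.9

    def test_same_seed_gives_identical_weights(self):
        cohort = separable_cohort()
        runs = []
        for _ in range(2):
            model = build_model(CFG, seed=1)
            train(model, cohort, TrainConfig(max_epochs=3, learning_rate=0.01,
                                             seed=5, augment=True))
            runs.append([p.copy() for p in model.params()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_missing_class_rejected(self):
        cohort = [c for c in separable_cohort() if c[1] != SurvivalLabel.MEDIUM]
        model = build_model(CFG, seed=1)
        with pytest.raises(ValueError, match="medium"):
            train(model, cohort, TrainConfig(max_epochs=1))

    def test_save_load_roundtrip(self, tmp_path, rng):
        cohort = separable_cohort()
        model = build_model(CFG, seed=1)
        train(model, cohort, TrainConfig(max_epochs=2, learning_rate=0.01,
                                         seed=3, augment=False))
        save_model(model, tmp_path / "model.npz")
        loaded = load_model(tmp_path / "model.npz")
        x = rng.random((16, 16, 8, 4))
        np.testing.assert_allclose(predict_scores(model, x).logits,
                                   predict_scores(loaded, x).logits,
                                   rtol=1e-6)
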