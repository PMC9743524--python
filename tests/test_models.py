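"""Architecture builders: structure, parameter counts, space validation, training."""

import numpy as np
import pytest

from crrpred import nn
from crrpred.encoding import one_hot_batch
from crrpred.evaluation import auroc
from crrpred.models import (
    ModelConfig, build_bayesian_cnn, build_bayesian_ffnn, build_deepenhancer,
    build_fixed_cnn, build_fixed_ffnn, build_model, train,
)
from crrpred.spaces import ConfigError, ffnn_hg19_space
from crrpred.synthetic import generate_dataset, benchmark_spec

FIXED_FFNN_POINT = {
    "n_dense": 3, "units_1": 16, "units_2": 4, "units_3": 2,
    "learning_rate": 0.5, "decay": 0.1, "l2": 0.0, "batch_size": 32.0,
    "epochs": 64.0,
}


class TestFixedFFNN:
    @pytest.mark.parametrize("input_dim,expected", [(101, 1713), (1, 113)])
    def test_parameter_counts(self, input_dim, expected):
        model, _ = build_fixed_ffnn(input_dim)
        assert model.n_params == expected

    def test_zero_weights_predict_half(self):
        model, _ = build_fixed_ffnn(5)
        model.set_weights([np.zeros_like(p) for p in model.params])
        out = model.predict(np.zeros((3, 5), np.float32))
        assert np.allclose(out, 0.5)

    def test_training_settings(self):
        _, s = build_fixed_ffnn(5)
        assert (s.optimizer, s.learning_rate, s.decay, s.l2) == ("sgd", 0.5, 0.1, 0.0)
        assert (s.batch_size, s.max_epochs) == (32, 64)

    def test_fixed_architecture_is_a_point_of_the_search_space(self):
        assert FIXED_FFNN_POINT in ffnn_hg19_space()


class TestBayesianFFNN:
    def test_hg19_pyramid_at_upper_boundary(self):
        params = dict(FIXED_FFNN_POINT, units_1=256, units_2=128, units_3=64)
        model, _ = build_bayesian_ffnn(ModelConfig("bayes_ffnn_hg19", params), 10)
        widths = [l.W.shape[1] for l in model.layers if isinstance(l, nn.Dense)]
        assert widths == [256, 128, 64, 1]

    def test_hg38_all_groups_empty_is_logistic_regression(self):
        params = {f"group{g}_layers": 0 for g in range(1, 5)}
        params.update({f"group{g}_dropout": 0.0 for g in range(1, 5)})
        params.update(learning_rate=0.2, decay=0.05, l2=0.0, batch_size=64.0, epochs=40.0)
        model, _ = build_bayesian_ffnn(ModelConfig("bayes_ffnn_hg38", params), 7)
        assert model.n_params == 8  # 7 weights + bias: input -> sigmoid

    def test_hg38_rectangular_widths_accepted_and_zero_width_skipped(self):
        params = {f"group{g}_layers": 0 for g in range(2, 5)}
        params.update({f"group{g}_dropout": 0.0 for g in range(1, 5)})
        params.update(group1_layers=3, group1_units_1=128, group1_units_2=128,
                      group1_units_3=0, group1_dropout=0.25,
                      learning_rate=0.2, decay=0.05, l2=0.0, batch_size=64.0,
                      epochs=40.0)
        model, _ = build_bayesian_ffnn(ModelConfig("bayes_ffnn_hg38", params), 7)
        widths = [l.W.shape[1] for l in model.layers if isinstance(l, nn.Dense)]
        assert widths == [128, 128, 1]  # zero-width third layer omitted
        assert any(isinstance(l, nn.Dropout) for l in model.layers)

    def test_out_of_space_config_names_dimension(self):
        params = dict(FIXED_FFNN_POINT, units_1=100)  # not in the choice set
        with pytest.raises(ConfigError, match="units_1"):
            build_bayesian_ffnn(ModelConfig("bayes_ffnn_hg19", params), 10)

    def test_same_config_builds_identical_model(self):
        cfg = ModelConfig("bayes_ffnn_hg19", FIXED_FFNN_POINT, seed=5)
        m1, _ = build_bayesian_ffnn(cfg, 10)
        m2, _ = build_bayesian_ffnn(cfg, 10)
        for a, b in zip(m1.params, m2.params):
            assert np.array_equal(a, b)


class TestFixedCNN:
    def test_layer_census(self):
        model, settings = build_fixed_cnn(200)
        summary = model.summary()
        assert summary.count("Conv1D") == 9
        assert summary.count("MaxPool1D") == 2
        assert summary.count("AvgPool1D") == 1
        assert (settings.optimizer, settings.learning_rate) == ("nadam", 0.002)

    def test_pooling_arithmetic_under_same_padding(self):
        model, _ = build_fixed_cnn(200)
        x = np.zeros((1, 200, 4), np.float32)
        lengths = []
        for layer in model.layers:
            x = layer.forward(x, train=False)
            if isinstance(layer, (nn.MaxPool1D, nn.AvgPool1D)):
                lengths.append(x.shape[1])
        assert lengths == [100, 50, 25]

    def test_untrained_scores_in_open_unit_interval(self):
        model, _ = build_fixed_cnn(64)
        x = np.random.default_rng(0).random((5, 64, 4)).astype(np.float32)
        out = model.predict(x)
        assert ((out > 0) & (out < 1)).all()

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_fixed_cnn(8)


HG19_CNN_POINT = {
    "filters_1": 128, "filters_2": 128, "filters_3": 128,
    "filters_4": 128, "kernel_4": 10, "dense_1": 10, "dense_2": 10,
}


class TestBayesianCNN:
    def test_hg19_kernel_choice_enforced(self):
        model, _ = build_bayesian_cnn(ModelConfig("bayes_cnn_hg19", HG19_CNN_POINT), 64)
        assert model.summary().count("Conv1D") == 4
        bad = dict(HG19_CNN_POINT, kernel_4=7)
        with pytest.raises(ConfigError, match="kernel_4"):
            build_bayesian_cnn(ModelConfig("bayes_cnn_hg19", bad), 64)

    def test_hg38_empty_config_is_flatten_to_sigmoid(self):
        params = {"n_conv_groups": 0, "n_dense_groups": 0}
        model, settings = build_bayesian_cnn(ModelConfig("bayes_cnn_hg38", params), 200)
        kinds = [type(l).__name__ for l in model.layers]
        assert kinds == ["Flatten", "Dense", "Sigmoid"]
        assert model.n_params == 200 * 4 + 1
        assert settings.l1 == settings.l2 == 1e-4

    def test_hg38_void_groups_are_skipped(self):
        params = {
            "n_conv_groups": 1, "conv1_layers": 2, "conv1_filters_1": 0,
            "conv1_filters_2": 8, "conv1_kernel_h": 4, "conv1_kernel_w": 2,
            "conv1_pool_h": 4, "conv1_pool_w": 1, "conv1_dropout": 0.0,
            "n_dense_groups": 1, "dense1_layers": 1, "dense1_units_1": 0,
            "dense1_dropout": 0.0,
        }
        model, _ = build_bayesian_cnn(ModelConfig("bayes_cnn_hg38", params), 40)
        summary = model.summary()
        assert summary.count("Conv2D") == 1  # zero-filter layer omitted
        assert summary.count("Dense") == 1  # only the sigmoid head
        x = np.zeros((2, 40, 4, 1), np.float32)
        assert model.predict(x).shape == (2,)


class TestDeepEnhancer:
    def test_layer_census_and_head(self):
        model, settings = build_deepenhancer(200)
        summary = model.summary()
        assert summary.count("Conv1D") == 4
        assert summary.count("BatchNorm") == 4
        assert summary.count("MaxPool1D") == 2
        dense = [l for l in model.layers if isinstance(l, nn.Dense)]
        assert [d.W.shape[1] for d in dense] == [256, 128, 1]
        assert isinstance(model.layers[-1], nn.Sigmoid)
        assert (settings.optimizer, settings.learning_rate, settings.max_epochs) == (
            "adam", 1e-4, 30)

    def test_alternate_window_lengths(self):
        for window in (200, 300):
            model, _ = build_deepenhancer(window)
            assert model.input_shape == (window, 4)


class TestTrainContract:
    def test_descent_on_separable_features(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(300, 2)).astype(np.float32)
        y = (x[:, 0] - x[:, 1] > 0).astype(int)
        model, settings = build_fixed_ffnn(2)
        hist = train(model, settings, x, y, seed=0, max_epochs=20)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_nonbinary_labels_rejected(self):
        model, settings = build_fixed_ffnn(2)
        with pytest.raises(ValueError):
            train(model, settings, np.zeros((4, 2), np.float32), np.array([0, 1, 2, 1]))

    def test_pure_noise_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        aurocs = []
        for seed in range(5):
            x = rng.normal(size=(400, 8)).astype(np.float32)
            y = rng.integers(0, 2, 400)
            model, settings = build_fixed_ffnn(8, seed=seed)
            train(model, settings, x[:300], y[:300], seed=seed, max_epochs=15)
            aurocs.append(auroc(y[300:], model.predict(x[300:])))
        assert 0.4 <= np.mean(aurocs) <= 0.6

    def test_batchnorm_cnn_learns_planted_motif(self):
        """A sequence model with batch normalization separates motif-bearing
        from background windows far above chance."""
        spec = benchmark_spec(n_total=2000, imbalance_ratio=1.0, embed_prob=1.0,
                               seed=9, window_length=100)
        _, seqs, _, y = generate_dataset(spec)
        x = one_hot_batch([r.sequence for r in seqs], 100)
        perm = np.random.default_rng(0).permutation(len(y))
        x, y = x[perm], y[perm]
        cfg = ModelConfig("bayes_cnn_hg19", {
            "filters_1": 32, "filters_2": 32, "filters_3": 32,
            "filters_4": 32, "kernel_4": 5, "dense_1": 32, "dense_2": 10,
        })
        model, settings = build_model(cfg, (100, 4))
        hist = train(model, settings, x[:1600], y[:1600], x[1600:], y[1600:],
                     seed=0, max_epochs=20)
        assert auroc(y[1600:], model.predict(x[1600:])) > 0.75
        assert hist.train_loss[-1] < 0.3
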