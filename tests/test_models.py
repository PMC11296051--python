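import numpy as np
import pytest

from pcedetect import nn
from pcedetect.dives import Dive
from pcedetect.models import (CnnConfig, TrainedModel, VnetConfig, build_cnn,
                              build_vnet, n_params, predict_points, train_cnn,
                              train_vnet)
from pcedetect.sampling import SamplerConfig, WindowBatch

RNG = np.random.default_rng(30)

TINY_VNET = dict(input_len=32, filters_per_level=(4, 6, 8), epochs=2,
                 batch_size=8)


def _toy_cnn_batch(n=120, snr=6.0, seed=0):
    """Linearly separable toy: positive windows carry a strong surge bump."""
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 1, size=(n, 8, 3))
    labels = (np.arange(n) % 2).astype(np.int64)
    data[labels == 1, 2:6, 0] += snr
    return WindowBatch(data=data, labels=labels)


class TestBuild:
    def test_cnn_output_is_a_probability_vector(self):
        model = build_cnn(CnnConfig(), seed=1)
        out = nn.softmax(model.forward(np.zeros((1, 8, 3))))
        assert out.shape == (1, 2)
        assert out.sum() == pytest.approx(1.0)

    def test_vnet_output_shape_and_row_normalization(self):
        model = build_vnet(VnetConfig(), seed=1)
        out = nn.softmax(model.forward(RNG.normal(size=(2, 128, 3))))
        assert out.shape == (2, 128, 2)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, rtol=1e-9)

    def test_indivisible_input_length_is_a_build_error(self):
        with pytest.raises(ValueError, match="divisible"):
            VnetConfig(input_len=100, encoder_levels=4,
                       filters_per_level=(4, 8, 16, 32))

    def test_kernel_pool_shape_arithmetic_enforced(self):
        with pytest.raises(ValueError):
            CnnConfig(window=8, n_conv_layers=3, kernel=2)  # post length 5

    def test_parameter_counts_reported(self):
        assert n_params(build_cnn(CnnConfig(), 0)) > 10000
        assert n_params(build_vnet(VnetConfig(**{**TINY_VNET, "epochs": 1}),
                                   0)) > 500


class TestTraining:
    def test_separable_toy_beats_class_prior_baseline(self):
        train = _toy_cnn_batch(seed=1)
        val = _toy_cnn_batch(seed=2)
        cfg = CnnConfig(epochs=10)
        tm = train_cnn(train, val, cfg, seed=0)
        prior = val.labels.mean()
        baseline = -(prior * np.log(prior) + (1 - prior) * np.log(1 - prior))
        assert min(h["val_loss"] for h in tm.history) < baseline

    def test_zero_epochs_returns_initialized_weights_and_empty_history(self):
        cfg = CnnConfig(epochs=0)
        tm = train_cnn(_toy_cnn_batch(), _toy_cnn_batch(), cfg, seed=3)
        ref = build_cnn(cfg, seed=3)
        for a, b in zip(tm.model.params(), ref.params()):
            np.testing.assert_array_equal(a.value, b.value)
        assert tm.history == []

    def test_identical_seeds_give_identical_histories(self):
        cfg = CnnConfig(epochs=3)
        h1 = train_cnn(_toy_cnn_batch(), _toy_cnn_batch(seed=9), cfg,
                       seed=5).history
        h2 = train_cnn(_toy_cnn_batch(), _toy_cnn_batch(seed=9), cfg,
                       seed=5).history
        assert h1 == h2

    def test_single_class_training_pool_is_an_error(self):
        batch = _toy_cnn_batch()
        batch.labels[:] = 0
        with pytest.raises(ValueError, match="single class"):
            train_cnn(batch, _toy_cnn_batch(), CnnConfig(), seed=0)

    def test_best_epoch_weights_are_retained(self):
        train = _toy_cnn_batch(seed=1)
        val = _toy_cnn_batch(seed=2)
        tm = train_cnn(train, val, CnnConfig(epochs=5), seed=0)
        best = min(h["val_loss"] for h in tm.history)
        assert tm.history[tm.best_epoch]["val_loss"] == best

    def test_vnet_trains_and_history_has_epoch_entries(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2000, 3))
        labels = np.zeros(2000, dtype=np.uint8)
        for c in (300, 700, 1200, 1700):
            labels[c - 3:c + 5] = 1
            data[c - 3:c + 5, 0] += 5
        pool = [("a", data, labels)]
        cfg = VnetConfig(**TINY_VNET)
        scfg = SamplerConfig(w_vnet=32, epoch_windows_train=64,
                             epoch_windows_val=32)
        tm = train_vnet(pool, pool, cfg, scfg, seed=1)
        assert len(tm.history) == cfg.epochs
        assert tm.best_epoch is not None


class TestPrediction:
    def _always_positive_cnn(self):
        cfg = CnnConfig(epochs=0)
        model = build_cnn(cfg, seed=0)
        # force the output layer to always vote class 1
        out = model.layers[-1]
        out.W.value[...] = 0.0
        out.b.value[...] = np.array([-5.0, 5.0])
        return TrainedModel(kind="cnn", model=model, config=cfg,
                            history=[{"epoch": 0}])

    def test_surface_series_gets_all_zero_predictions(self):
        tm = self._always_positive_cnn()
        n = 600
        pred = predict_points(tm, RNG.normal(size=(n, 3)), np.zeros(n), [])
        assert not pred.any()

    def test_always_positive_model_marks_exactly_in_dive_samples(self):
        tm = self._always_positive_cnn()
        n = 600
        depth = np.zeros(n)
        depth[100:300] = 10.0
        dives = [Dive(dive_id=0, start_idx=100, end_idx=300, max_depth_m=10,
                      duration_s=8)]
        pred = predict_points(tm, RNG.normal(size=(n, 3)), depth, dives)
        assert pred[100:300].all()
        assert not pred[:100].any() and not pred[300:].any()

    def test_cnn_union_marking_arithmetic(self):
        # a transparent stand-in classifier: positive iff the window's
        # summed surge exceeds a threshold, isolating the union arithmetic
        class SurgeSum:
            def forward(self, x, **kw):
                s = x[:, :, 0].sum(axis=1)
                return np.stack([np.zeros_like(s), s - 60.0], axis=1)

            def params(self):
                return []

        cfg = CnnConfig(epochs=0)
        tm = TrainedModel(kind="cnn", model=SurgeSum(), config=cfg,
                          history=[{"epoch": 0}])
        n = 400
        depth = np.full(n, 10.0)
        dives = [Dive(dive_id=0, start_idx=0, end_idx=n, max_depth_m=10,
                      duration_s=16)]

        # 8-sample bump fully inside exactly one step-4 window -> 8 marked
        data = np.zeros((n, 3))
        data[100:108, 0] = 10.0  # sums: window 96 -> 40, 100 -> 80, 104 -> 40
        marked = np.flatnonzero(predict_points(tm, data, depth, dives))
        assert list(marked) == list(range(100, 108))

        # 12-sample bump -> two overlapping positive windows -> 12 marked
        data = np.zeros((n, 3))
        data[100:112, 0] = 10.0  # windows 100 and 104 sum to 80 each
        marked = np.flatnonzero(predict_points(tm, data, depth, dives))
        assert list(marked) == list(range(100, 112))

    def test_vnet_tiling_discards_padded_outputs(self):
        cfg = VnetConfig(**{**TINY_VNET, "epochs": 0})
        model = build_vnet(cfg, seed=0)
        head = model.head
        head.W.value[...] = 0.0
        head.b.value[...] = np.array([-1.0, 1.0])  # always predict capture
        tm = TrainedModel(kind="vnet", model=model, config=cfg,
                          history=[{"epoch": 0}])
        n = 300
        depth = np.full(n, 10.0)
        dives = [Dive(dive_id=0, start_idx=10, end_idx=90, max_depth_m=10,
                      duration_s=3.2)]  # 80 samples: 2 full 32-tiles + 16
        pred = predict_points(tm, RNG.normal(size=(n, 3)), depth, dives)
        assert pred[10:90].all()
        assert not pred[:10].any() and not pred[90:].any()

    def test_untrained_model_refuses_to_predict(self):
        cfg = CnnConfig(epochs=10)
        tm = TrainedModel(kind="cnn", model=build_cnn(cfg, 0), config=cfg)
        with pytest.raises(ValueError, match="not been trained"):
            predict_points(tm, np.zeros((100, 3)), np.zeros(100), [])


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        tm = train_cnn(_toy_cnn_batch(seed=1), _toy_cnn_batch(seed=2),
                       CnnConfig(epochs=2), seed=4)
        tm.save(tmp_path / "cnn")
        back = TrainedModel.load(tmp_path / "cnn")
        x = RNG.normal(size=(5, 8, 3))
        np.testing.assert_array_equal(tm.model.forward(x),
                                      back.model.forward(x))
        assert back.history == tm.history

    def test_vnet_round_trip(self, tmp_path):
        cfg = VnetConfig(**{**TINY_VNET, "epochs": 0})
        tm = TrainedModel(kind="vnet", model=build_vnet(cfg, 7), config=cfg,
                          history=[], seed=7)
        tm.save(tmp_path / "v")
        back = TrainedModel.load(tmp_path / "v")
        x = RNG.normal(size=(2, 32, 3))
        np.testing.assert_array_equal(tm.model.forward(x),
                                      back.model.forward(x))
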