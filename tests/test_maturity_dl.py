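"""CNN-LSTM regressor: loss, architecture, GDD, augmentation, splitting."""

import numpy as np
import pytest

from beanpheno.geoplots import FlightRecord, PlotImageSeries
from beanpheno.maturity_dl import (ModelConfig, augment_stack, build_cnn_lstm,
                                   cumulative_gdd, huber_loss, split_dataset,
                                   train, train_with_restarts)
from beanpheno.synth import SenescenceParams, gen_maturity_image_stack


class TestHuberLoss:
    @pytest.mark.parametrize("r, expected", [
        (0.0, 0.0),
        (0.05, 0.00125),            # quadratic zone: 0.5 * 0.05^2
        (1.0, 0.095),               # linear zone: 0.1 * (1 - 0.05)
    ])
    def test_piecewise_values(self, r, expected):
        assert huber_loss([r], [0.0], sigma=0.1) == pytest.approx(expected)

    def test_matches_bruteforce_piecewise_on_random_residuals(self, rng):
        sigma = 0.1
        r = rng.normal(0, 2, size=500)
        per = np.where(np.abs(r) <= sigma, 0.5 * r ** 2,
                       sigma * (np.abs(r) - 0.5 * sigma))
        assert huber_loss(r, np.zeros_like(r), sigma) == pytest.approx(per.mean())
        # quadratic zone bounded by MSE/2; linear growth beyond
        small = r[np.abs(r) <= sigma]
        if small.size:
            assert huber_loss(small, np.zeros_like(small), sigma) <= (small ** 2).mean() / 2 + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            huber_loss([1.0, 2.0], [1.0], sigma=0.1)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            huber_loss([1.0], [1.0], sigma=0.0)


def _param_count_oracle(cfg: ModelConfig) -> int:
    """Layer-by-layer closed-form count, independent of the implementation."""
    h, w = cfg.image_size
    total, cin = 0, 3
    for f in cfg.filters:
        total += (cfg.kernel ** 2 * cin + 1) * f
        cin = f
    feat = (h // 16) * (w // 16) * cfg.filters[-1]
    if cfg.use_gdd:
        total += (1 + 1) * cfg.gdd_units
        feat += cfg.gdd_units
    u = cfg.lstm_units
    total += 4 * (feat * u + u * u + u)
    total += u + 1
    return total


class TestBuildCnnLstm:
    def test_forward_shape_contract(self):
        cfg = ModelConfig(image_size=(64, 256), filters=(4, 4, 4, 4), lstm_units=8)
        model = build_cnn_lstm(cfg)
        x = np.zeros((1, 6, 64, 256, 3), dtype=np.uint8)
        assert model.forward(x).shape == (1,)

    def test_same_seed_identical_weights(self):
        cfg = ModelConfig(image_size=(16, 16), filters=(2, 2, 2, 2), lstm_units=4, seed=9)
        m1, m2 = build_cnn_lstm(cfg), build_cnn_lstm(cfg)
        assert all(np.array_equal(a, b) for a, b in zip(m1.params, m2.params))

    @pytest.mark.parametrize("cfg", [
        ModelConfig(image_size=(64, 256), filters=(8, 16, 32, 64), lstm_units=64),
        ModelConfig(image_size=(16, 16), filters=(2, 3, 4, 5), lstm_units=6),
        ModelConfig(image_size=(128, 512), filters=(16, 32, 64, 128), lstm_units=256),
        ModelConfig(image_size=(32, 128), filters=(4, 8, 16, 32), lstm_units=16,
                    use_gdd=True, gdd_units=8),
    ])
    def test_parameter_count_matches_closed_form(self, cfg):
        assert build_cnn_lstm(cfg).n_parameters == _param_count_oracle(cfg)

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(image_size=(60, 250))

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = ModelConfig(image_size=(16, 16), filters=(2, 2, 2, 2), lstm_units=4)
        m = build_cnn_lstm(cfg)
        m.label_mean, m.label_std = 80.0, 6.0
        path = tmp_path / "model.npz"
        m.save(path)
        from beanpheno.maturity_dl import CNNLSTM
        loaded = CNNLSTM.load(path)
        x = np.random.default_rng(0).random((2, 3, 16, 16, 3)).astype(np.float32)
        assert np.allclose(loaded.forward(x), m.forward(x))


class TestCumulativeGdd:
    def test_single_day_arithmetic(self):
        g = cumulative_gdd([20.0], [30.0], np.array([1]), tbase=10.0)
        assert g.cumulative[0] == pytest.approx(15.0)

    def test_floor_at_zero(self):
        g = cumulative_gdd([0.0] * 20, [5.0] * 20, np.array([10, 20]), tbase=10.0)
        assert np.allclose(g.cumulative, 0.0)

    def test_constant_rate_accumulation(self):
        g = cumulative_gdd([20.0] * 20, [30.0] * 20, np.array([10, 20]), tbase=10.0)
        assert np.allclose(g.cumulative, [150.0, 300.0])

    def test_gap_in_dates_rejected(self):
        dates = np.array(["2022-07-01", "2022-07-02", "2022-07-04"], dtype="datetime64[D]")
        with pytest.raises(ValueError, match="gaps"):
            cumulative_gdd([20.0] * 3, [30.0] * 3, np.array([1]), dates=dates)

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            cumulative_gdd([20.0] * 5, [30.0] * 5, np.array([10]))


def _tiny_stack(n_plots=4, n_flights=3, size=(16, 16), seed=0):
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 255, (n_flights, n_plots) + size + (3,), dtype=np.uint8)
    flights = [FlightRecord(f"d{i}", 60 + 8 * i, 0.5) for i in range(n_flights)]
    return PlotImageSeries(data, flights, [f"P{i}" for i in range(n_plots)])


class TestAugmentStack:
    def test_fraction_zero_identity(self):
        stack = _tiny_stack()
        out, applied = augment_stack(stack, 0.0, seed=1)
        assert np.array_equal(out.data, stack.data)
        assert applied == {}

    def test_exact_plot_count_modified(self):
        stack = _tiny_stack(n_plots=10)
        _, applied = augment_stack(stack, 0.2, seed=2)
        assert len(applied) == 2

    def test_brightness_shift_per_pixel_oracle(self):
        stack = _tiny_stack(n_plots=1)
        stack.data[:] = 100
        out, applied = augment_stack(stack, 1.0, seed=5, brightness_delta=30)
        if applied[0] == "brightness":
            assert np.all(np.isin(out.data, (70, 130)))

    def test_labels_axis_untouched(self):
        stack = _tiny_stack()
        out, _ = augment_stack(stack, 0.5, seed=3)
        assert out.plot_ids == stack.plot_ids
        assert out.data.shape == stack.data.shape


class TestSplitDataset:
    def test_stratification_arithmetic(self):
        env = np.repeat([0, 1], 50)
        split = split_dataset(np.zeros(100), test_fraction=0.2,
                              environment_ids=env, seed=0)
        assert (env[split.test] == 0).sum() == 10
        assert (env[split.test] == 1).sum() == 10
        # partitions disjoint and exhaustive
        combined = np.concatenate([split.train, split.val, split.test])
        assert sorted(combined) == list(range(100))

    def test_seed_reproducible(self):
        env = np.repeat([0, 1], 20)
        a = split_dataset(np.zeros(40), environment_ids=env, seed=7)
        b = split_dataset(np.zeros(40), environment_ids=env, seed=7)
        assert np.array_equal(a.test, b.test) and np.array_equal(a.train, b.train)

    def test_zero_test_fraction(self):
        split = split_dataset(np.zeros(20), test_fraction=0.0, seed=1)
        assert split.test.size == 0
        assert split.train.size + split.val.size == 20

    def test_tiny_environment_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(np.zeros(3), environment_ids=[0, 0, 1])


class TestTrainPredict:
    def test_zero_epochs_empty_history(self):
        stack = _tiny_stack()
        cfg = ModelConfig(image_size=(16, 16), filters=(2, 2, 2, 2), lstm_units=4,
                          epochs=0)
        model = build_cnn_lstm(cfg)
        result = train(model, stack, [70.0, 75, 80, 85], cfg)
        assert result.train_loss == []

    def test_deterministic_loss_history(self):
        stack = _tiny_stack()
        labels = [70.0, 75, 80, 85]
        cfg = ModelConfig(image_size=(16, 16), filters=(2, 2, 2, 2), lstm_units=4,
                          epochs=3, batch_size=2, seed=11)
        r1 = train(build_cnn_lstm(cfg), stack, labels, cfg)
        r2 = train(build_cnn_lstm(cfg), stack, labels, cfg)
        assert r1.train_loss == r2.train_loss

    def test_duplicated_plots_get_identical_predictions(self):
        stack = _tiny_stack(n_plots=2)
        cfg = ModelConfig(image_size=(16, 16), filters=(2, 2, 2, 2), lstm_units=4)
        model = build_cnn_lstm(cfg)
        block = stack.data.transpose(1, 0, 2, 3, 4)
        doubled = np.concatenate([block, block])
        pred = model.forward(doubled)
        assert np.allclose(pred[:2], pred[2:])

    def test_wrong_image_size_rejected(self):
        cfg = ModelConfig(image_size=(16, 16), filters=(2, 2, 2, 2), lstm_units=4)
        model = build_cnn_lstm(cfg)
        with pytest.raises(ValueError, match="image size"):
            model.predict(np.zeros((1, 3, 32, 32, 3)))

    def test_small_overfit_reduces_error(self):
        # small-scale counterpart of the 64x256 overfit check in
        # tests/test_acceptance.py
        p = SenescenceParams(n_plots=16, seed=11)
        stack, truth = gen_maturity_image_stack(p, image_size=(16, 64))
        cfg = ModelConfig(image_size=(16, 64), filters=(8, 16, 32, 64), lstm_units=64,
                          batch_size=4, learning_rate=3e-3, decay=0.0,
                          dropout=0.0, seed=11)
        _, result = train_with_restarts(stack, truth, cfg, target_train_mae=0.8,
                                        max_attempts=6, attempt_epochs=80)
        assert result.final_train_mae < 1.5

    def test_gdd_fusion_forward_and_training_step(self):
        stack = _tiny_stack(n_plots=4, n_flights=3)
        cfg = ModelConfig(image_size=(16, 16), filters=(2, 2, 2, 2), lstm_units=4,
                          epochs=2, batch_size=2, use_gdd=True, gdd_units=4)
        model = build_cnn_lstm(cfg)
        gdd = np.array([120.0, 260.0, 410.0])
        result = train(model, stack, [70.0, 75, 80, 85], cfg, gdd=gdd)
        assert len(result.train_loss) == 2
        pred = model.predict(stack, gdd=gdd)
        assert pred.shape == (4,)
        with pytest.raises(ValueError):
            model.forward(stack.data.transpose(1, 0, 2, 3, 4))  # GDD missing
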