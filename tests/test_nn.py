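"""Neural estimators: architectures, gradients, training, predictions."""

import numpy as np
import pytest

import decaymap as dm
from decaymap.nn import (
    AdamW,
    CNNSpec,
    NN1DSpec,
    TrainConfig,
    build_cnn,
    build_nn1d,
    count_trainable_params,
    extract_pixel_curves,
    mse_loss,
    predict_map,
    train_model,
)
from decaymap.nn.layers import Dense

from conftest import per_slice_accuracy


class TestArchitectures:
    def test_nn1d_parameter_count_exact(self):
        assert count_trainable_params(build_nn1d()) == 17_474

    def test_single_affine_layer_contribution(self):
        layer = Dense(10, 64, np.random.default_rng(0))
        assert sum(p.value.size for p in layer.parameters()) == 10 * 64 + 64

    def test_frozen_parameters_not_counted(self):
        model = build_nn1d()
        for p in model.parameters():
            p.trainable = False
        assert count_trainable_params(model) == 0

    def test_cnn_reference_parameter_count(self):
        assert count_trainable_params(build_cnn()) == 6_950_457

    def test_same_seed_identical_init(self):
        a, b = build_nn1d(seed=4), build_nn1d(seed=4)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = build_nn1d(seed=5)
        assert any(
            not np.array_equal(pa.value, pc.value)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    def test_cnn_preserves_spatial_shape(self):
        model = build_cnn(CNNSpec.scaled_down(), seed=0)
        for size in (16, 32, 64):  # fully convolutional
            out = model(np.zeros((1, 10, size, size)))
            assert out.shape == (1, 2, size, size)

    def test_bad_channel_stride_combo_rejected(self):
        with pytest.raises(ValueError):
            CNNSpec(channels=(8, 8), strides=(2, 2))


class TestGradients:
    def _check(self, model, x, y, n_probe=30, seed=0):
        model.train()
        model.zero_grad()
        loss, g = mse_loss(model(x), y)
        model.backward(g)
        params = model.parameters()
        rng = np.random.default_rng(seed)
        eps = 1e-6
        for _ in range(n_probe):
            p = params[rng.integers(len(params))]
            idx = (
                tuple(rng.integers(s) for s in p.value.shape)
                if p.value.shape
                else ()
            )
            orig = p.value[idx]
            p.value[idx] = orig + eps
            lp, _ = mse_loss(model(x), y)
            p.value[idx] = orig - eps
            lm, _ = mse_loss(model(x), y)
            p.value[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - p.grad[idx]) <= 1e-7 + 1e-4 * (abs(num) + abs(p.grad[idx]))

    def test_mlp_backprop_matches_numeric(self):
        model = build_nn1d(seed=5)
        rng = np.random.default_rng(1)
        self._check(model, rng.normal(size=(13, 10)), rng.normal(size=(13, 2)))

    def test_cnn_backprop_matches_numeric(self):
        spec = CNNSpec(channels=(4, 4, 6, 8), strides=(2, 2, 2), num_res_units=2)
        model = build_cnn(spec, seed=3)
        rng = np.random.default_rng(2)
        self._check(
            model, rng.normal(size=(3, 10, 16, 16)), rng.normal(size=(3, 2, 16, 16))
        )


class TestExtractCurves:
    def test_tiny_dataset_counts_and_targets(self, schedule):
        cfg = dm.SynthConfig(n_series=1, size=2, mode="urand", seed=1)
        recs = dm.build_synthetic_dataset(cfg)
        curves, targets = extract_pixel_curves(recs)
        assert curves.shape == (4, 10) and targets.shape == (4, 2)
        np.testing.assert_array_equal(targets[:, 0], recs[0].truth.s0.reshape(-1))
        np.testing.assert_array_equal(targets[:, 1], recs[0].truth.t.reshape(-1))

    def test_count_scales_with_records(self, small_records):
        curves, _ = extract_pixel_curves(small_records)
        assert curves.shape[0] == len(small_records) * 8 * 8

    def test_row_major_record_major_order(self, schedule):
        recs = dm.build_synthetic_dataset(
            dm.SynthConfig(n_series=2, size=3, mode="urand", seed=2)
        )
        curves, _ = extract_pixel_curves(recs)
        np.testing.assert_array_equal(curves[:9], recs[0].series.data.reshape(9, 10))
        np.testing.assert_array_equal(curves[9:], recs[1].series.data.reshape(9, 10))

    def test_schedule_mismatch_rejected(self, schedule, small_records):
        other = dm.EchoSchedule(eta=np.linspace(0.1, 1, 10))
        bad = dm.SynthRecord(
            series=dm.ImageSeries(small_records[0].series.data, other),
            truth=small_records[0].truth,
            sigma=0.01,
        )
        with pytest.raises(ValueError):
            extract_pixel_curves([small_records[0], bad])


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self, small_records):
        model = build_nn1d(seed=1)
        before = model.state()
        history = train_model(model, small_records, TrainConfig(epochs=0, seed=0))
        assert history.train_loss == [] and history.val_loss == []
        for a, b in zip(before, model.state()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_histories(self, small_records):
        h = []
        for _ in range(2):
            model = build_nn1d(seed=2)
            h.append(
                train_model(
                    model, small_records, TrainConfig(epochs=3, batch_size=64, seed=5)
                )
            )
        assert h[0].train_loss == h[1].train_loss
        assert h[0].val_loss == h[1].val_loss

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_diagnostic(self, small_records):
        model = build_nn1d(seed=3)
        with pytest.raises(RuntimeError, match="diverged"):
            train_model(
                model,
                small_records,
                TrainConfig(epochs=50, batch_size=64, lr=1e6, seed=0),
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(val_frac=1.5)

    def test_training_reduces_validation_loss(self, trained):
        # supervised smoke oracle on the scaled-down preset
        cnn_hist = trained["cnn_history"]
        assert cnn_hist.best_val_loss < 0.1 * cnn_hist.val_loss[0]
        nn1d_hist = trained["nn1d_history"]
        assert nn1d_hist.best_val_loss < 0.6 * nn1d_hist.val_loss[0]


class TestPrediction:
    def test_untrained_model_rejected(self, schedule, rng):
        model = build_nn1d(seed=0)
        series = dm.ImageSeries(rng.uniform(0, 1, (4, 4, 10)), schedule)
        with pytest.raises(ValueError):
            predict_map(model, series)

    def test_schedule_mismatch_rejected(self, trained, rng):
        other = dm.EchoSchedule(eta=np.linspace(0.1, 1, 10))
        series = dm.ImageSeries(rng.uniform(0, 1, (32, 32, 10)), other)
        with pytest.raises(ValueError):
            predict_map(trained["nn1d"], series)

    def test_indivisible_spatial_dims_rejected(self, trained, rng):
        series = dm.ImageSeries(
            rng.uniform(0, 1, (20, 20, 10)), trained["cnn"].schedule
        )
        with pytest.raises(ValueError):
            predict_map(trained["cnn"], series)

    def test_nn1d_series_equals_pixelwise_curves(self, trained, rng):
        model = trained["nn1d"]
        series = dm.ImageSeries(rng.uniform(0, 1, (6, 6, 10)), model.schedule)
        pmap = predict_map(model, series)
        out = model(series.data.reshape(-1, 10))
        np.testing.assert_array_equal(pmap.s0.reshape(-1), out[:, 0])
        np.testing.assert_array_equal(pmap.t.reshape(-1), out[:, 1])

    def test_prediction_deterministic_in_eval(self, trained):
        series = trained["corpus_test"][0].series
        a = predict_map(trained["cnn"], series)
        b = predict_map(trained["cnn"], series)
        np.testing.assert_array_equal(a.t, b.t)


class TestEstimatorComparison:
    """The supervised-denoising ordering and range-confinement mechanisms."""

    def test_accuracy_ordering_on_correlated_data(self, trained):
        # CNN (spatial prior) beats per-pixel NN1D beats unbounded NLLS
        accs = {"cnn": [], "nn1d": [], "nlls": []}
        for rec in trained["corpus_test"][:30]:
            accs["cnn"].append(
                per_slice_accuracy(predict_map(trained["cnn"], rec.series), rec.truth)
            )
            accs["nn1d"].append(
                per_slice_accuracy(predict_map(trained["nn1d"], rec.series), rec.truth)
            )
            accs["nlls"].append(
                per_slice_accuracy(dm.fit_nlls(rec.series).map, rec.truth)
            )
        med = {k: float(np.median(v)) for k, v in accs.items()}
        assert med["cnn"] < med["nn1d"] < med["nlls"]

    def test_nn1d_training_range_confinement(self, trained, rng):
        # wild (non-decay) curves in the input intensity range: predictions
        # stay inside the training T range, unlike an unbounded fit
        model = trained["nn1d"]
        series = dm.ImageSeries(rng.uniform(0, 1, (64, 64, 10)), model.schedule)
        t_pred = predict_map(model, series).t
        assert np.mean((t_pred > -0.5) & (t_pred < 5.0)) >= 0.99

    def test_cnn_bounded_where_fit_diverges(self, trained):
        # non-decaying series: NLLS wants T -> infinity, the trained CNN
        # emits values near its training range (implicit bounds, softly)
        img = dm.procedural_corpus(1, size=32, seed=99)[0]
        series = dm.ImageSeries(
            np.repeat(img[:, :, None], 10, axis=2), trained["cnn"].schedule
        )
        noisy = dm.add_rician_noise(series, dm.NoiseSpec(0.05, seed=3))
        t_cnn = predict_map(trained["cnn"], noisy).t
        t_nlls = dm.fit_nlls(noisy).map.t
        assert np.all(np.isfinite(t_cnn))
        assert t_cnn.max() < 3 * 4.0
        # the unbounded fit explodes (or goes nonpositive) on many pixels
        wild_frac = np.mean((~np.isfinite(t_nlls)) | (t_nlls > 12.0) | (t_nlls <= 0))
        assert wild_frac > 0.2


class TestOptimizer:
    def test_adamw_decays_unused_weights(self):
        from decaymap.nn.layers import Parameter

        param = Parameter(np.array([1.0]))
        opt = AdamW([param], lr=0.1, weight_decay=0.5)
        param.grad[...] = 0.0
        opt.step()
        assert param.value[0] < 1.0  # decoupled decay acts even at zero gradient

    def test_invalid_lr_rejected(self):
        from decaymap.nn.layers import Parameter

        with pytest.raises(ValueError):
            AdamW([Parameter(np.zeros(1))], lr=0.0)
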