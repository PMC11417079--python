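"""Error summaries, SSIM, binned error surfaces, noise-addition experiment."""

import numpy as np
import pytest
from scipy import ndimage

import decaymap as dm
from decaymap.evaluate import T_DATA_RANGE


def naive_ssim(a, b, data_range, sigma=1.5, win=11):
    """Direct windowed SSIM (Gaussian weights, population statistics)."""
    truncate = (win // 2) / sigma  # radius 5 -> 11-tap window
    f = lambda x: ndimage.gaussian_filter(x, sigma, truncate=truncate, mode="reflect")
    k1, k2 = 0.01, 0.03
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a**2
    vb = f(b * b) - mu_b**2
    cov = f(a * b) - mu_a * mu_b
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    )
    pad = win // 2
    return float(ssim_map[pad:-pad, pad:-pad].mean())


def pmap(t, s0=None):
    t = np.asarray(t, dtype=float)
    return dm.ParameterMap(np.ones_like(t) if s0 is None else s0, t)


class TestSummarizeErrors:
    def test_identical_maps(self, rng):
        t = rng.uniform(0.045, 4, (32, 32))
        s = dm.summarize_errors(pmap(t), pmap(t))
        assert s.bias == 0 and s.precision == 0 and s.accuracy == 0 and s.ssim == 1.0

    def test_constant_shift(self, rng):
        t = rng.uniform(1, 2, (32, 32))
        s = dm.summarize_errors(pmap(t + 0.1), pmap(t))
        assert s.bias == pytest.approx(0.1)
        assert s.precision == pytest.approx(0.0, abs=1e-12)
        assert s.accuracy == pytest.approx(0.1)

    def test_alternating_half_half(self):
        t = np.full((4, 4), 1.0)
        delta = np.indices((4, 4)).sum(axis=0) % 2  # checkerboard: half 0, half 1
        pred = t + 0.1 * (2 * delta - 1)  # half +0.1, half -0.1
        s = dm.summarize_errors(pmap(pred), pmap(t))
        assert s.bias == pytest.approx(0.0)
        assert s.accuracy == pytest.approx(0.1)
        assert s.precision == pytest.approx(0.2)

    def test_mask_restricts_pixels(self, rng):
        t = np.ones((8, 8))
        pred = t.copy()
        pred[0, 0] = 5.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[4:, 4:] = True
        s = dm.summarize_errors(pmap(pred), pmap(t), mask=mask)
        assert s.bias == 0.0 and s.accuracy == 0.0

    def test_empty_mask_rejected(self):
        t = np.ones((4, 4))
        with pytest.raises(ValueError):
            dm.summarize_errors(pmap(t), pmap(t), mask=np.zeros((4, 4), dtype=bool))

    def test_median_stats_permutation_invariant_ssim_not(self, rng):
        t = rng.uniform(0.045, 4, (16, 16))
        pred = t + rng.normal(0, 0.2, t.shape)
        perm = rng.permutation(t.size)
        t2 = t.reshape(-1)[perm].reshape(t.shape)
        p2 = pred.reshape(-1)[perm].reshape(t.shape)
        a = dm.summarize_errors(pmap(pred), pmap(t))
        b = dm.summarize_errors(pmap(p2), pmap(t2))
        assert a.bias == pytest.approx(b.bias)
        assert a.precision == pytest.approx(b.precision)
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.ssim != pytest.approx(b.ssim, abs=1e-6)


class TestSsim:
    def test_identity_and_symmetry(self, rng):
        a = rng.uniform(0, 4, (32, 32))
        b = rng.uniform(0, 4, (32, 32))
        assert dm.ssim_score(a, a) == 1.0
        assert dm.ssim_score(a, b) == pytest.approx(dm.ssim_score(b, a), rel=1e-12)

    def test_matches_direct_implementation(self):
        truth = np.tile(np.linspace(0.045, 4.0, 64), (64, 1))
        pred = (4.0 + 0.045) - truth  # inverted ramp
        ours = dm.ssim_score(pred, truth)
        ref = naive_ssim(truth, pred, T_DATA_RANGE)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_equal_constants_score_one(self):
        a = np.full((16, 16), 2.0)
        assert dm.ssim_score(a, a.copy()) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dm.ssim_score(np.zeros((4, 4)), np.zeros((5, 5)))


class TestBinErrors:
    def test_constant_error_everywhere(self, rng):
        snr = rng.uniform(0, 50, 1000)
        t = rng.uniform(0.045, 4, 1000)
        err = np.full(1000, 0.3)
        surf = dm.bin_errors(err, snr, t, n_bins=10)
        nonempty = surf.counts_vs_snr > 0
        np.testing.assert_allclose(surf.median_vs_snr[nonempty], 0.3)
        np.testing.assert_allclose(surf.iqr_vs_snr[nonempty], 0.0)

    def test_counts_sum_to_finite_pixels(self, rng):
        n = 500
        snr = rng.uniform(0, 40, n)
        snr[:50] = -np.inf  # the s0 = 0 sentinel
        err = rng.normal(size=n)
        t = rng.uniform(0.045, 4, n)
        surf = dm.bin_errors(err, snr, t, n_bins=8)
        assert surf.n_finite == n - 50
        assert surf.counts_vs_snr.sum() == n - 50
        assert surf.counts_vs_t.sum() == n - 50

    def test_uniform_snr_fills_bins_evenly(self, rng):
        n, bins = 100_000, 100
        snr = rng.uniform(0, 50, n)
        err = rng.normal(size=n)
        t = rng.uniform(0.045, 4, n)
        surf = dm.bin_errors(err, snr, t, n_bins=bins)
        expected = n / bins
        # multinomial: sd ~ sqrt(n/bins); allow 5 sigma
        assert np.all(np.abs(surf.counts_vs_snr - expected) < 5 * np.sqrt(expected) + 1)

    def test_no_finite_pixels_rejected(self):
        with pytest.raises(ValueError):
            dm.bin_errors(np.ones(4), np.full(4, -np.inf), np.ones(4))


@pytest.fixture(scope="module")
def tiny_series():
    cfg = dm.SynthConfig(n_series=3, size=16, mode="urand", seed=6,
                         sigma_range=(0.001, 0.01))
    return [dm.normalize_series(r.series) for r in dm.build_synthetic_dataset(cfg)]


class TestNoiseAdditionExperiment:

    def test_zero_level_is_identically_perfect(self, tiny_series):
        methods = {"loglin": lambda s: dm.fit_loglin(s).map}
        res = dm.noise_addition_experiment(
            tiny_series, methods, sigma_levels=(0.0,), seed=1
        )
        assert np.allclose(res.frame["bias"], 0.0)
        assert np.allclose(res.frame["accuracy"], 0.0)
        assert np.allclose(res.frame["ssim"], 1.0)

    def test_accuracy_grows_with_added_noise(self, tiny_series):
        methods = {"loglin": lambda s: dm.fit_loglin(s).map}
        res = dm.noise_addition_experiment(
            tiny_series, methods, sigma_levels=(0.02, 0.05, 0.08), seed=2
        )
        acc = res.summary().sort_values("sigma_added")["accuracy"].to_numpy()
        assert np.all(np.diff(acc) > 0)

    def test_unnormalized_series_rejected(self, schedule, rng):
        series = dm.ImageSeries(rng.uniform(0, 0.5, (16, 16, 10)), schedule)
        with pytest.raises(ValueError, match="normalized"):
            dm.noise_addition_experiment(
                [series], {"loglin": lambda s: dm.fit_loglin(s).map}
            )

    def test_added_noise_estimable_and_monotone(self, schedule):
        # residual-based sigma of the augmented series grows with sigma_added
        # and is at least the added level (noise adds in quadrature)
        s0 = np.full((24, 24), 0.9)
        t = np.full((24, 24), 1.0)
        clean = dm.ImageSeries(dm.decay_signal(s0, t, schedule), schedule)
        base = dm.normalize_series(clean)
        est = []
        for sig in (0.02, 0.05, 0.08):
            aug = dm.add_rician_noise(base, dm.NoiseSpec(sig, seed=4))
            est.append(float(np.median(dm.estimate_sigma_map(aug, dm.fit_nlls(aug)))))
        assert est[0] < est[1] < est[2]
        for sig, e in zip((0.02, 0.05, 0.08), est):
            assert e > 0.8 * sig


class TestPlotting:
    def test_figures_render(self, rng):
        import pandas as pd

        from decaymap.plotting import plot_binned_surface, plot_error_boxes

        frame = pd.DataFrame(
            {
                "method": ["a"] * 5 + ["b"] * 5,
                "accuracy": rng.uniform(0, 1, 10),
            }
        )
        ax = plot_error_boxes(frame)
        assert ax.get_ylabel() == "accuracy"
        surf = dm.bin_errors(
            rng.normal(size=500), rng.uniform(0, 40, 500), rng.uniform(0.045, 4, 500),
            n_bins=10,
        )
        ax = plot_binned_surface(surf)
        assert ax.get_xlabel() == "T_true"
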