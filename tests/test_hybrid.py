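"""Hybrid construction, probe curves, and reversal-frequency estimation."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from freqlens.hybrid import (
    ProbeCurve,
    build_hybrid_dataset,
    default_fmix_grid,
    lowpass_mask,
    make_hybrid,
    probe_classifier,
    reversal_frequency,
    sample_pairs,
)
from freqlens.models import ConstantClassifier
from freqlens.synthdata import BandDatasetSpec, make_band_dataset, make_oracle_classifier


class TestLowpassMask:
    def test_zero_cutoff_keeps_only_dc(self):
        m = lowpass_mask(8, 8, 0.0)
        assert m.values.sum() == 1
        assert m.values[4, 4] == 1

    def test_cutoff_above_sqrt2_is_all_pass(self):
        assert lowpass_mask(8, 8, np.sqrt(2) + 1e-9).values.all()

    def test_bin_count_matches_enumeration(self):
        m = lowpass_mask(32, 32, 0.5)
        fy = np.fft.fftshift(np.fft.fftfreq(32)) * 2
        count = sum(
            1 for a in fy for b in fy if np.sqrt(a * a + b * b) <= 0.5
        )
        assert int(m.values.sum()) == count

    def test_point_symmetric_about_dc(self):
        v = lowpass_mask(16, 16, 0.7).values
        # fftshift-centered grids of even size are symmetric under index negation
        shifted = np.fft.ifftshift(v)
        np.testing.assert_array_equal(shifted, np.roll(shifted[::-1, ::-1], (1, 1), (0, 1)))

    def test_negative_cutoff_raises(self):
        with pytest.raises(ValueError):
            lowpass_mask(8, 8, -0.1)


class TestMakeHybrid:
    def test_self_mix_identity(self, rng):
        img = rng.random((16, 16))
        for f in (0.0, 0.4, 1.0):
            assert np.abs(make_hybrid(img, img, f).pixels - img).max() < 1e-6

    def test_full_mask_returns_low_seed(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert np.abs(make_hybrid(a, b, 1.5).pixels - a).max() < 1e-10

    def test_zero_mask_keeps_high_seed_except_dc(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        h = make_hybrid(a, b, 0.0).pixels
        assert np.abs((h - h.mean()) - (b - b.mean())).max() < 1e-10
        assert h.mean() == pytest.approx(a.mean())

    @pytest.mark.parametrize("f_mix", [0.2, 0.6, 1.1])
    def test_parseval_split(self, f_mix, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        h = make_hybrid(a, b, f_mix).pixels
        mask = np.fft.ifftshift(lowpass_mask(16, 16, f_mix).values).astype(bool)
        FA, FB, FH = np.fft.fft2(a), np.fft.fft2(b), np.fft.fft2(h)
        in_pow = lambda F: (np.abs(F[mask]) ** 2).sum()
        out_pow = lambda F: (np.abs(F[~mask]) ** 2).sum()
        assert in_pow(FH) == pytest.approx(in_pow(FA), rel=1e-6)
        assert out_pow(FH) == pytest.approx(out_pow(FB), rel=1e-6)

    def test_complementary_mixes_sum_to_seed_sum(self, rng):
        a, b = rng.random((12, 12)), rng.random((12, 12))
        h1 = make_hybrid(a, b, 0.5).pixels
        h2 = make_hybrid(b, a, 0.5).pixels
        np.testing.assert_allclose(h1 + h2, a + b, atol=1e-10)

    def test_rgb_channels_mixed_independently(self, rng):
        a, b = rng.random((8, 8, 3)), rng.random((8, 8, 3))
        h = make_hybrid(a, b, 0.6).pixels
        for c in range(3):
            np.testing.assert_allclose(
                h[:, :, c], make_hybrid(a[:, :, c], b[:, :, c], 0.6).pixels, atol=1e-12
            )

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            make_hybrid(rng.random((8, 8)), rng.random((4, 4)), 0.5)


class TestBuildHybridDataset:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.images = [rng.random((8, 8)) for _ in range(40)]
        self.labels = np.repeat(np.arange(4), 10)

    def test_pairs_have_distinct_labels(self):
        hybrids = build_hybrid_dataset(self.images, self.labels, [0.3, 0.6], 20, seed=0)
        assert all(h.low_label != h.high_label for h in hybrids)

    def test_deterministic_given_seed(self):
        h1 = build_hybrid_dataset(self.images, self.labels, [0.5], 10, seed=9)
        h2 = build_hybrid_dataset(self.images, self.labels, [0.5], 10, seed=9)
        for a, b in zip(h1, h2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
            assert (a.low_seed_id, a.high_seed_id) == (b.low_seed_id, b.high_seed_id)

    def test_same_pairs_reused_across_grid(self):
        hybrids = build_hybrid_dataset(self.images, self.labels, [0.2, 0.8], 15, seed=1)
        first = [(h.low_seed_id, h.high_seed_id) for h in hybrids[:15]]
        second = [(h.low_seed_id, h.high_seed_id) for h in hybrids[15:]]
        assert first == second

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            build_hybrid_dataset(self.images[:10], np.zeros(10), [0.5], 5, seed=0)

    def test_class_pair_distribution_uniform(self):
        labels = np.repeat(np.arange(4), 10)
        pairs = sample_pairs(labels, 1200, np.random.default_rng(0))
        counts = {}
        for lo, hi in pairs:
            key = (labels[lo], labels[hi])
            counts[key] = counts.get(key, 0) + 1
        observed = [counts.get((i, j), 0) for i in range(4) for j in range(4) if i != j]
        assert chisquare(observed).pvalue > 0.01


class TestProbeAndReversal:
    def test_constant_model_saturates_p_low(self, rng):
        images = [rng.random((8, 8)) for _ in range(10)]
        labels = [0] * 5 + [1] * 5
        hybrids = [
            h
            for h in build_hybrid_dataset(images, labels, [0.3, 0.9], 20, seed=0)
            if h.low_label == 0
        ]
        model = ConstantClassifier(2, (8, 8), label=0)
        curve = probe_classifier(model, hybrids)
        np.testing.assert_array_equal(curve.p_low, 1.0)
        np.testing.assert_array_equal(curve.p_high, 0.0)

    def test_linear_difference_crossing_is_exact(self):
        grid = np.linspace(0, 1, 11)
        d = 2 * grid - 1
        p_low = (1 + d) / 2
        curve = ProbeCurve(grid, p_low, 1 - p_low, np.full(11, 10), np.nan, False)
        est = reversal_frequency(curve)
        assert est.f_rev == pytest.approx(0.5)
        assert not est.censored

    def test_never_crossing_curve_is_censored(self):
        grid = np.linspace(0, 1, 5)
        curve = ProbeCurve(grid, np.zeros(5), np.ones(5), np.full(5, 10), np.nan, False)
        est = reversal_frequency(curve)
        assert est.censored and np.isnan(est.f_rev)

    def test_swap_mirrors_curve(self):
        """Relabeling each hybrid's seeds as their complements swaps p_low/p_high.

        A hybrid built from (low=a, high=b) with mask M is pixel-identical to
        one built from (low=b, high=a) with the complementary mask, so
        swapping the recorded roles must mirror the probe curve exactly.
        """
        from freqlens.hybrid import HybridImage

        spec = BandDatasetSpec(
            n_classes=2,
            images_per_class=20,
            size=(16, 16),
            class_bands=((0.1, 0.5), (0.6, 1.0)),
            noise_std=0.05,
            amplitude_slope=0.0,
            noise_exponent=0.0,
            seed=1,
        )
        ds = make_band_dataset(spec)
        oracle = make_oracle_classifier(ds.templates, 0.7)
        hybrids = build_hybrid_dataset(list(ds.images), ds.labels, [0.3, 0.7, 1.1], 40, seed=2)
        swapped = [
            HybridImage(h.pixels, h.f_mix, h.high_label, h.low_label, h.high_seed_id, h.low_seed_id)
            for h in hybrids
        ]
        cf, cb = probe_classifier(oracle, hybrids), probe_classifier(oracle, swapped)
        np.testing.assert_allclose(cf.p_low, cb.p_high, atol=1e-12)
        np.testing.assert_allclose(cf.p_high, cb.p_low, atol=1e-12)

    def test_cnn_probe_trend_monotone(self, easy2_dataset, easy2_cnn):
        ds = easy2_dataset
        test = ds.images[160:], ds.labels[160:]
        hybrids = build_hybrid_dataset(
            list(test[0]), test[1], default_fmix_grid(9), 60, seed=4
        )
        curve = probe_classifier(easy2_cnn, hybrids)
        d = curve.p_low - curve.p_high
        # The curve saturates at +-1, producing ties, so rank correlation is
        # computed on the distinct-value trend plus an isotonic-fit check.
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression().fit_transform(curve.f_mix_grid, d)
        assert np.mean((d - iso) ** 2) < 1e-3  # curve is monotone up to noise
        assert d[-1] - d[0] > 1.5  # full reversal from high-seed to low-seed
        keep = np.concatenate([[True], np.diff(d) != 0])
        rho = spearmanr(curve.f_mix_grid[keep], d[keep]).statistic
        assert rho > 0.9

    def test_grid_refinement_stability(self):
        spec = BandDatasetSpec(
            n_classes=4,
            images_per_class=30,
            class_bands=((0.05, 0.95),) * 4,
            template_components=4,
            noise_std=0.05,
            amplitude_slope=0.0,
            noise_exponent=0.0,
            seed=3,
        )
        ds = make_band_dataset(spec)
        oracle = make_oracle_classifier(ds.templates, 0.5)
        coarse_grid = default_fmix_grid(9)
        fine_grid = default_fmix_grid(17)
        f_rev = {}
        for name, grid in (("coarse", coarse_grid), ("fine", fine_grid)):
            hybrids = build_hybrid_dataset(list(ds.images), ds.labels, grid, 150, seed=6)
            f_rev[name] = probe_classifier(oracle, hybrids).f_rev
        spacing = coarse_grid[1] - coarse_grid[0]
        assert abs(f_rev["fine"] - f_rev["coarse"]) < spacing
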