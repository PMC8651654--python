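"""Binarized pairwise synchrony, shuffle control, epoch/category/distance
restrictions."""

import numpy as np
import pytest
from scipy import stats

from catrack import correlate
from catrack.behavior import detect_whisk_epochs, whisk_response_windows
from catrack.correlate import (
    BinaryRaster,
    binarize_trace,
    category_restricted_correlation,
    correlation_vs_distance,
    epoch_restricted_correlation,
    pairwise_correlation,
    shuffle_control,
)
from catrack.simulate import simulate_binary_raster


def phi_from_table(x, y):
    """Phi coefficient from the 2x2 co-occurrence table (oracle)."""
    n11 = np.sum((x == 1) & (y == 1))
    n10 = np.sum((x == 1) & (y == 0))
    n01 = np.sum((x == 0) & (y == 1))
    n00 = np.sum((x == 0) & (y == 0))
    denom = np.sqrt(
        float(n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    return (n11 * n00 - n10 * n01) / denom


class TestBinarize:
    def test_all_zero_trace(self, conditioned_factory):
        cond = conditioned_factory(np.zeros(500))
        assert binarize_trace(cond).sum() == 0

    def test_block_crossing_threshold(self, conditioned_factory):
        x = np.zeros(500)
        x[100:130] = 10.0
        cond = conditioned_factory(x)
        out = binarize_trace(cond, smooth_frames=1, k_sd=2)
        assert out[100:130].all()
        assert out.sum() == 30

    def test_scale_invariance(self, conditioned_factory, rng):
        x = rng.normal(0, 1, 1000)
        x[200:260] += 6.0
        a = binarize_trace(conditioned_factory(x, noise_sd=1.0))
        b = binarize_trace(conditioned_factory(10 * x, noise_sd=10.0))
        np.testing.assert_array_equal(a, b)

    def test_zero_noise_refused(self, conditioned_factory):
        with pytest.raises(ValueError):
            binarize_trace(conditioned_factory(np.zeros(10), noise_sd=0.0))


class TestPairwiseCorrelation:
    def test_identical_vectors_give_one(self):
        v = np.zeros(300, dtype=np.uint8)
        v[50:80] = 1
        res = pairwise_correlation(BinaryRaster(np.column_stack([v, v]), 10.0))
        assert res.r[0] == pytest.approx(1.0)

    def test_matches_phi_coefficient_exactly(self, rng):
        data = (rng.uniform(size=(400, 6)) < 0.2).astype(np.uint8)
        res = pairwise_correlation(BinaryRaster(data, 10.0))
        for k, (i, j) in enumerate(res.pairs):
            if np.isfinite(res.r[k]):
                assert res.r[k] == pytest.approx(
                    phi_from_table(data[:, i], data[:, j]), abs=1e-12
                )

    def test_independent_null_near_zero(self):
        rng = np.random.default_rng(0)
        data = (rng.uniform(size=(5000, 50)) < 0.05).astype(np.uint8)
        res = pairwise_correlation(BinaryRaster(data, 10.0))
        assert -0.01 <= res.mean_r <= 0.01

    def test_constant_vectors_flagged_and_excluded(self):
        rng = np.random.default_rng(1)
        data = (rng.uniform(size=(300, 3)) < 0.2).astype(np.uint8)
        data[:, 2] = 0  # constant neuron
        res = pairwise_correlation(BinaryRaster(data, 10.0))
        assert res.n_excluded == 2
        assert np.isfinite(res.r).sum() == 1

    def test_short_frame_mask_flags_fov(self):
        data = np.ones((300, 3), dtype=np.uint8)
        mask = np.zeros(300, dtype=bool)
        mask[:50] = True
        res = pairwise_correlation(BinaryRaster(data, 10.0), frame_mask=mask)
        assert not res.valid

    def test_order_invariance(self, rng):
        data = (rng.uniform(size=(1000, 8)) < 0.1).astype(np.uint8)
        res = pairwise_correlation(BinaryRaster(data, 10.0))
        perm = rng.permutation(8)
        res_p = pairwise_correlation(BinaryRaster(data[:, perm], 10.0))
        assert res.mean_r == pytest.approx(res_p.mean_r, abs=1e-12)


class TestShuffleControl:
    def test_seeded_reproducibility(self, rng):
        data = (rng.uniform(size=(600, 10)) < 0.1).astype(np.uint8)
        raster = BinaryRaster(data, 10.0)
        a = shuffle_control(raster, n_shuffles=10, seed=3)
        b = shuffle_control(raster, n_shuffles=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_null_mean_near_zero_and_converges(self):
        rng = np.random.default_rng(2)
        means = []
        for n_frames in (500, 2000, 5000):
            r = simulate_binary_raster(20, n_frames, participation_p=0.4, seed=11)
            null = shuffle_control(r, n_shuffles=30, seed=1)
            means.append(abs(np.nanmean(null)))
            se = np.nanstd(null) / np.sqrt(30)
            assert abs(np.nanmean(null)) <= max(2 * se, 0.01)
        assert means[-1] <= means[0] + 0.005  # tighter with more frames

    def test_destroys_shared_structure(self):
        r = simulate_binary_raster(30, 5000, participation_p=0.4, seed=4)
        actual = pairwise_correlation(r).mean_r
        null = shuffle_control(r, n_shuffles=20, seed=0)
        assert actual > np.nanmean(null) + 5 * np.nanstd(null)


class TestEpochRestriction:
    def test_full_mask_equals_unrestricted(self, rng):
        data = (rng.uniform(size=(800, 5)) < 0.15).astype(np.uint8)
        raster = BinaryRaster(data, 10.0)
        full = pairwise_correlation(raster)
        by_epoch = epoch_restricted_correlation(
            raster, {"all": np.ones(800, dtype=bool)}
        )
        np.testing.assert_allclose(by_epoch["all"].r, full.r, atol=1e-12)

    def test_whisk_synchrony_detected_in_whisk_epochs(self):
        # shared events occur only during whisk-associated frames
        track = np.zeros(6000, dtype=np.uint8)
        for s in range(0, 6000, 300):
            track[s : s + 10] = 1
        es = detect_whisk_epochs(track, 10.0)
        assoc, _ = whisk_response_windows(es)
        whisk_frames = es.mask("whisk") | assoc
        r = simulate_binary_raster(
            30,
            6000,
            rate_per_min=1.0,
            shared_rate_per_min=8.0,
            participation_p=0.5,
            seed=6,
            whisk_mask=whisk_frames,
        )
        res = epoch_restricted_correlation(
            r, {"whisk": whisk_frames, "stationary": ~whisk_frames}
        )
        assert res["whisk"].mean_r > res["stationary"].mean_r


class TestDistanceDependence:
    def test_single_bin_recovers_overall_mean(self, rng):
        data = (rng.uniform(size=(1000, 6)) < 0.2).astype(np.uint8)
        cent = rng.uniform(0, 100, size=(6, 2))
        res = pairwise_correlation(BinaryRaster(data, 10.0, centroids_um=cent))
        df = correlation_vs_distance(res, [0.0, 200.0])
        assert df["mean_r"].iloc[0] == pytest.approx(res.mean_r)

    def test_decay_with_distance(self):
        rng = np.random.default_rng(9)
        cent = rng.uniform(0, 200, size=(60, 2))
        r = simulate_binary_raster(
            60,
            8000,
            rate_per_min=1.0,
            shared_rate_per_min=8.0,
            participation_p=0.9,
            seed=9,
            centroids_um=cent,
            spatial_scale_um=40.0,
        )
        res = pairwise_correlation(r)
        df = correlation_vs_distance(res, np.arange(0, 250, 50.0))
        means = df["mean_r"].dropna().to_numpy()
        rho = stats.spearmanr(np.arange(len(means)), means).statistic
        assert rho <= -0.9

    def test_empty_bin_flagged(self, rng):
        data = (rng.uniform(size=(500, 4)) < 0.2).astype(np.uint8)
        cent = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        res = pairwise_correlation(BinaryRaster(data, 10.0, centroids_um=cent))
        df = correlation_vs_distance(res, [0.0, 10.0, 20.0])
        assert df["n_pairs"].iloc[1] == 0
        assert np.isnan(df["mean_r"].iloc[1])
        assert df.attrs["covers_all_bins"] is False


class TestCategoryRestriction:
    def test_pair_combinatorics(self, rng):
        # 3 high + 2 intermediate neurons: 3 high-high pairs, 1 int-int pair
        data = (rng.uniform(size=(500, 5)) < 0.3).astype(np.uint8)
        res = pairwise_correlation(BinaryRaster(data, 10.0))
        cats = {0: "high", 1: "high", 2: "high", 3: "intermediate", 4: "intermediate"}
        assert len(category_restricted_correlation(res, cats, "high")) == 3
        assert len(category_restricted_correlation(res, cats, "intermediate")) == 1

    def test_no_high_cells_empty(self, rng):
        data = (rng.uniform(size=(500, 3)) < 0.3).astype(np.uint8)
        res = pairwise_correlation(BinaryRaster(data, 10.0))
        cats = {0: "rare", 1: "rare", 2: "intermediate"}
        assert len(category_restricted_correlation(res, cats, "high")) == 0

    def test_filter_then_mean_consistency(self, rng):
        data = (rng.uniform(size=(800, 6)) < 0.25).astype(np.uint8)
        res = pairwise_correlation(BinaryRaster(data, 10.0))
        cats = {i: ("high" if i < 4 else "rare") for i in range(6)}
        vals = category_restricted_correlation(res, cats, "high")
        manual = [
            res.r[k]
            for k, (i, j) in enumerate(res.pairs)
            if i < 4 and j < 4 and np.isfinite(res.r[k])
        ]
        assert np.mean(vals) == pytest.approx(np.mean(manual))


class TestMonotoneSynchrony:
    def test_mean_r_increases_with_participation(self):
        means = []
        for i, p in enumerate((0.0, 0.1, 0.2, 0.3, 0.4)):
            r = simulate_binary_raster(50, 5000, participation_p=p, seed=10 + i)
            means.append(pairwise_correlation(r).mean_r)
        rho = stats.spearmanr(np.arange(5), means).statistic
        assert rho >= 0.95
        assert all(b > a for a, b in zip(means, means[1:]))
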