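"""Plaque channel cleanup, binarization, 3D distances and stratified
dynamics."""

import numpy as np
import pandas as pd
import pytest

from catrack import plaques
from catrack.plaques import (
    PlaqueDistanceRecord,
    PlaqueVolume,
    RoiGeometry,
    binarize_plaques,
    classify_proximity,
    clean_methoxy_channel,
    nearest_plaque_distance,
    proximity_stratified_dynamics,
)
from catrack.simulate import (
    appps1_like_population,
    random_distance_records,
    render_structural_channels,
    simulate_plaque_volume,
    simulate_rate_table,
)


class TestCleanup:
    def test_flat_background_maps_to_zero(self, rng):
        m = np.full((4, 32, 32), 20.0)
        g = np.zeros((4, 32, 32))
        cleaned = clean_methoxy_channel(m, g)
        assert np.abs(cleaned).max() == pytest.approx(0.0, abs=1e-9)

    def test_bleed_through_removed(self):
        # a bright object present equally in both channels disappears
        m = np.full((2, 40, 40), 20.0)
        g = np.full((2, 40, 40), 10.0)
        m[0, 10:20, 10:20] += 50.0
        g[0, 10:20, 10:20] += 50.0
        cleaned = clean_methoxy_channel(m, g)
        assert cleaned[0, 12:18, 12:18].max() <= 1.0

    def test_plaque_only_object_preserved(self):
        m = np.full((2, 40, 40), 20.0)
        g = np.full((2, 40, 40), 10.0)
        m[0, 10:20, 10:20] += 50.0
        cleaned = clean_methoxy_channel(m, g)
        assert cleaned[0, 12:18, 12:18].min() >= 0.9 * 50.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clean_methoxy_channel(np.zeros((2, 4, 4)), np.zeros((2, 4, 5)))


class TestBinarize:
    def test_pure_noise_low_positive_fraction(self, rng):
        stack = rng.normal(10.0, 2.0, (6, 128, 128))
        vol = binarize_plaques(stack)
        assert vol.mask.mean() <= 0.02  # Gaussian tail beyond robust 3 sigma

    def test_bright_disk_recovered(self, rng):
        stack = rng.normal(10.0, 2.0, (3, 128, 128))
        yy, xx = np.mgrid[:128, :128]
        disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2
        stack[1][disk] += 20.0  # 10 sigma above background
        vol = binarize_plaques(stack)
        inter = (vol.mask[1] & disk).sum()
        union = (vol.mask[1] | disk).sum()
        assert inter / union >= 0.9

    def test_all_zero_frame_no_positives(self):
        vol = binarize_plaques(np.zeros((2, 16, 16)))
        assert vol.mask.sum() == 0

    def test_end_to_end_raw_channel_recovery(self, rng):
        # render raw channels with bleed-through, clean, binarize, compare
        truth = simulate_plaque_volume(
            np.array([[20.0, 20.0, 8.0]]), [6.0], shape_voxels=(32, 64, 64)
        )
        chans = render_structural_channels(truth, seed=2)
        cleaned = clean_methoxy_channel(chans["methoxy"], chans["gcamp"])
        vol = binarize_plaques(cleaned)
        inter = (vol.mask & truth.mask).sum()
        union = (vol.mask | truth.mask).sum()
        assert inter / union >= 0.7


class TestDistances:
    def test_centroid_on_positive_voxel(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[5, 5, 5] = True
        vol = PlaqueVolume(mask, voxel_size_um=(1.0, 1.0, 1.0))
        assert nearest_plaque_distance(RoiGeometry(0, (5.0, 5.0, 5.0)), vol) == 0.0

    def test_single_voxel_along_x(self):
        mask = np.zeros((5, 5, 50), dtype=bool)
        mask[2, 2, 40] = True  # x = 40 um at unit voxels
        vol = PlaqueVolume(mask, voxel_size_um=(1.0, 1.0, 1.0))
        d = nearest_plaque_distance(RoiGeometry(0, (10.0, 2.0, 2.0)), vol)
        assert d == pytest.approx(30.0)

    def test_empty_mask_is_infinite(self):
        vol = PlaqueVolume(np.zeros((4, 4, 4), dtype=bool))
        d = nearest_plaque_distance(RoiGeometry(0, (1.0, 1.0, 1.0)), vol)
        assert np.isinf(d)
        assert classify_proximity(d) == "distant"

    def test_matches_brute_force_on_random_anisotropic_volumes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            shape = tuple(rng.integers(8, 30, 3))
            vs = tuple(rng.uniform(0.3, 1.5, 3))
            mask = rng.uniform(size=shape) < 0.02
            vol = PlaqueVolume(mask, voxel_size_um=vs)
            c = tuple(rng.uniform(0, 15, 3))
            d = nearest_plaque_distance(RoiGeometry(0, c), vol)
            coords = vol.positive_coords_um()
            if coords.shape[0] == 0:
                assert np.isinf(d)
            else:
                brute = np.sqrt(((coords - np.array(c)) ** 2).sum(axis=1)).min()
                assert d == pytest.approx(brute, abs=1e-9)

    def test_monotone_under_mask_growth(self, rng):
        mask = rng.uniform(size=(12, 12, 12)) < 0.02
        vol = PlaqueVolume(mask.copy(), voxel_size_um=(0.7, 0.7, 0.5))
        roi = RoiGeometry(0, (3.0, 3.0, 2.0))
        d1 = nearest_plaque_distance(roi, vol)
        mask2 = mask | (rng.uniform(size=mask.shape) < 0.05)
        d2 = nearest_plaque_distance(roi, PlaqueVolume(mask2, voxel_size_um=(0.7, 0.7, 0.5)))
        assert d2 <= d1

    def test_translation_invariance(self, rng):
        mask = rng.uniform(size=(10, 14, 14)) < 0.03
        vs = (0.673, 0.673, 0.5)
        c = (4.0, 5.0, 2.0)
        d0 = nearest_plaque_distance(RoiGeometry(0, c), PlaqueVolume(mask, vs))
        shift = (7.3, -2.1, 4.4)
        vol_t = PlaqueVolume(mask, vs, origin_um=shift)
        c_t = tuple(np.add(c, shift))
        d1 = nearest_plaque_distance(RoiGeometry(0, c_t), vol_t)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestProximityClass:
    @pytest.mark.parametrize(
        "d,expected",
        [(40.0, "close"), (40.1, "distant"), (0.0, "close"), (np.inf, "distant")],
    )
    def test_cutoff(self, d, expected):
        assert classify_proximity(d) == expected

    def test_alternative_cutoffs(self):
        assert classify_proximity(50.0, cutoff_um=60.0) == "close"
        assert classify_proximity(50.0, cutoff_um=20.0) == "distant"


class TestStratifiedDynamics:
    def _table(self, seed=0, n=300):
        pop = appps1_like_population(n)
        return simulate_rate_table(pop, n_sessions=2, drift_sd=1.0, seed=seed)

    def test_all_distant_equals_unstratified(self):
        from catrack import dynamics as dyn

        t = self._table()
        n = t["neuron_id"].nunique()
        recs = [
            PlaqueDistanceRecord(i, s, 90.0) for i in range(n) for s in (0, 1)
        ]
        out = proximity_stratified_dynamics(t, recs)
        assert out["strata"]["close"]["n_neurons"] == 0
        assert out["strata"]["distant"]["n_neurons"] == n
        np.testing.assert_allclose(
            np.sort(out["strata"]["distant"]["delta_rate"]),
            np.sort(dyn.activity_change(t, 0, 1).to_numpy()),
        )

    def test_close_persistence_enforced_generator(self):
        """High-category neurons near plaques with small drift persist more."""
        from catrack.detect import classify_activity

        rng = np.random.default_rng(6)
        rows, recs = [], []
        for i in range(400):
            close = i < 200
            r0 = rng.uniform(4.5, 10.0)  # all start highly active
            drift_sd = 0.3 if close else 3.0  # persistence near plaques
            r1 = abs(r0 + rng.normal(0, drift_sd))
            d = rng.uniform(5, 35) if close else rng.uniform(45, 95)
            for s, r in ((0, r0), (1, r1)):
                rows.append(
                    {
                        "neuron_id": i,
                        "session_id": s,
                        "rate": r,
                        "auc": np.nan,
                        "category": classify_activity(r),
                        "fov_id": 0,
                        "cohort": "",
                    }
                )
                recs.append(PlaqueDistanceRecord(i, s, d))
        out = proximity_stratified_dynamics(pd.DataFrame(rows), recs)
        assert (
            out["strata"]["close"]["reoccurrence"]["high"]
            > out["strata"]["distant"]["reoccurrence"]["high"]
        )

    def test_neurons_missing_a_session_excluded(self):
        t = self._table(n=50)
        recs = random_distance_records(range(50), [0, 1], seed=1)
        # neuron 0 loses its session-1 record
        recs = [r for r in recs if not (r.neuron_id == 0 and r.session_id == 1)]
        out = proximity_stratified_dynamics(t, recs)
        total = sum(v["n_neurons"] for v in out["strata"].values())
        assert total == 49

    def test_distance_bins_mode(self):
        t = self._table(n=400)
        recs = random_distance_records(range(400), [0, 1], seed=2)
        out = proximity_stratified_dynamics(
            t, recs, bin_edges_um=np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        )
        assert len(out["strata"]) == 4
        assert len(out["ks_between_strata"]) == 3
        for v in out["ks_between_strata"].values():
            assert 0.0 <= v["p"] <= 1.0
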