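import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ws2pet.io import Volume
from ws2pet.ws2 import (WS2Config, WS2Error, ball_offsets, neighbor_counts,
                        pair_weight, sample_pairs, subject_seed, ws2_curve,
                        ws2_exhaustive, ws2_from_pairs)

from _oracles import brute_force_pairs


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=float), np.diag([*spacing, 1.0]))


class TestPairWeight:
    def test_equal_values_return_the_common_value(self):
        assert pair_weight(3.2, 3.2) == pytest.approx(3.2)

    def test_closed_form_two_zero(self):
        # mean 1, |diff| 2, lambda 1 -> e^-2
        assert pair_weight(2.0, 0.0, 1.0) == pytest.approx(np.exp(-2.0))

    @given(a=st.floats(0, 5), b=st.floats(0, 5), lam=st.floats(0.1, 10))
    def test_symmetry(self, a, b, lam):
        assert pair_weight(a, b, lam) == pair_weight(b, a, lam)

    def test_closer_values_weigh_more_at_equal_mean(self):
        assert pair_weight(1.1, 0.9) > pair_weight(1.5, 0.5) > pair_weight(2, 0)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(WS2Error):
            pair_weight(1.0, 1.0, 0.0)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_pairs": 0}, {"r_max": 0.0}, {"bin_width": 0.0},
        {"bin_width": 11.0}, {"lambda_diff": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(WS2Error):
            WS2Config(**kwargs)


class TestGeometry:
    @pytest.mark.parametrize("spacing,r_max", [
        ((1.0, 1.0, 1.0), 2.0),
        ((2.0, 2.0, 2.0), 5.0),
        ((1.0, 2.0, 3.0), 4.0),
    ])
    def test_ball_offsets_match_brute_force(self, spacing, r_max):
        offs = {tuple(o) for o in ball_offsets(spacing, r_max)}
        reach = [int(r_max // s) for s in spacing]
        expected = set()
        for i in range(-reach[0], reach[0] + 1):
            for j in range(-reach[1], reach[1] + 1):
                for k in range(-reach[2], reach[2] + 1):
                    d = np.linalg.norm(np.array([i, j, k]) * spacing)
                    if 0 < d <= r_max:
                        expected.add((i, j, k))
        assert offs == expected

    def test_neighbor_counts_match_brute_force(self):
        rng = np.random.default_rng(4)
        mask = rng.uniform(size=(6, 6, 6)) < 0.4
        counts = neighbor_counts(mask, (1.0, 1.0, 1.0), 2.0)
        pairs = brute_force_pairs(mask, (1.0, 1.0, 1.0), 2.0)
        expected = np.zeros_like(counts)
        for a, b, _ in pairs:
            expected[a] += 1
            expected[b] += 1
        np.testing.assert_array_equal(counts, expected)
        assert counts[~mask].sum() == 0


class TestSamplePairs:
    def test_two_voxel_mask_always_returns_that_pair(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 3] = True
        cfg = WS2Config(n_pairs=10, r_max=3.0, bin_width=1.0, seed=1)
        i1, i2, d = sample_pairs(mask, (1.0, 1.0, 1.0), cfg)
        np.testing.assert_allclose(d, 2.0)
        pairs = {frozenset((tuple(a), tuple(b))) for a, b in zip(i1, i2)}
        assert pairs == {frozenset(((1, 1, 1), (1, 1, 3)))}

    def test_contract_in_mask_and_within_range(self, small_phantom):
        mask = small_phantom.compartments["target_gm"]
        cfg = WS2Config(n_pairs=2000, seed=9)
        i1, i2, d = sample_pairs(mask, small_phantom.pet.spacing, cfg)
        assert mask[tuple(i1.T)].all() and mask[tuple(i2.T)].all()
        assert np.all(d > 0) and np.all(d <= cfg.r_max)
        assert not np.any(np.all(i1 == i2, axis=1))

    def test_seeded_runs_are_identical(self, small_phantom):
        mask = small_phantom.compartments["target_gm"]
        cfg = WS2Config(n_pairs=500, seed=33)
        a = sample_pairs(mask, small_phantom.pet.spacing, cfg)
        b = sample_pairs(mask, small_phantom.pet.spacing, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_different_seeds_differ(self, small_phantom):
        mask = small_phantom.compartments["target_gm"]
        a = sample_pairs(mask, small_phantom.pet.spacing,
                         WS2Config(n_pairs=500, seed=1))
        b = sample_pairs(mask, small_phantom.pet.spacing,
                         WS2Config(n_pairs=500, seed=2))
        assert not np.array_equal(a[0], b[0])

    def test_sampling_is_uniform_over_valid_pairs(self):
        # 3x3 slab: boundary voxels have fewer in-ball neighbours, so a
        # naive uniform first draw would over-represent their pairs.
        mask = np.zeros((3, 3, 1), dtype=bool)
        mask[:, :, 0] = True
        pairs = brute_force_pairs(mask, (1.0, 1.0, 1.0), 1.5)
        cfg = WS2Config(n_pairs=40_000, r_max=1.5, bin_width=1.5, seed=12)
        i1, i2, _ = sample_pairs(mask, (1.0, 1.0, 1.0), cfg)
        keys = [frozenset((tuple(a), tuple(b))) for a, b in zip(i1, i2)]
        freq = {frozenset((a, b)): 0 for a, b, _ in pairs}
        for k in keys:
            freq[k] += 1
        counts = np.array(list(freq.values()))
        expected = cfg.n_pairs / len(pairs)
        assert counts.min() > 0.85 * expected
        assert counts.max() < 1.15 * expected

    def test_mask_too_small_is_error(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(WS2Error, match="at least 2"):
            sample_pairs(mask, (1.0, 1.0, 1.0), WS2Config(n_pairs=5))

    def test_no_pair_within_range_is_error(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0, 0, 0] = mask[9, 9, 9] = True
        with pytest.raises(WS2Error, match="r_max"):
            sample_pairs(mask, (1.0, 1.0, 1.0), WS2Config(n_pairs=5, r_max=3))


class TestExhaustive:
    def test_uniform_image_gives_constant_bins_and_auc(self):
        vol = _vol(np.full((8, 8, 8), 1.7))
        mask = np.ones((8, 8, 8), dtype=bool)
        curve = ws2_exhaustive(vol, mask, r_max=4.0, bin_width=1.0)
        occ = ~curve.empty_bins
        np.testing.assert_allclose(curve.values[occ], 1.7, rtol=1e-12)
        span = curve.bin_centers[-1] - curve.bin_centers[0]
        assert curve.auc == pytest.approx(1.7 * span, rel=1e-12)

    def test_two_voxel_closed_form(self):
        data = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 2] = True
        data[0, 0, 0] = 2.0
        with pytest.warns(UserWarning, match="empty"):
            curve = ws2_exhaustive(_vol(data), mask, r_max=3.0,
                                   bin_width=1.0, lambda_diff=1.0)
        occ = ~curve.empty_bins
        assert occ.sum() == 1
        assert curve.values[occ][0] == pytest.approx(np.exp(-2.0))
        assert curve.counts[occ][0] == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0.5, 2.0, size=(5, 5, 5))
        mask = rng.uniform(size=(5, 5, 5)) < 0.6
        curve = ws2_exhaustive(_vol(data), mask, r_max=3.0, bin_width=1.0)
        pairs = brute_force_pairs(mask, (1.0, 1.0, 1.0), 3.0)
        sums = np.zeros(3)
        counts = np.zeros(3, dtype=int)
        for a, b, d in pairs:
            k = min(int(d), 2)
            sums[k] += pair_weight(data[a], data[b], 1.0)
            counts[k] += 1
        np.testing.assert_array_equal(curve.counts, counts)
        np.testing.assert_allclose(
            curve.values[counts > 0], sums[counts > 0] / counts[counts > 0],
            rtol=1e-12)

    def test_voxel_guard(self):
        vol = _vol(np.ones((20, 20, 20)))
        with pytest.raises(WS2Error, match="limited"):
            ws2_exhaustive(vol, np.ones((20, 20, 20), bool), max_voxels=100)


class TestMonteCarlo:
    def test_matches_exhaustive_within_three_stderr(self, blob_volume):
        vol, mask = blob_volume
        ex = ws2_exhaustive(vol, mask, r_max=6.0, bin_width=1.0)
        mc = ws2_curve(vol, mask, WS2Config(n_pairs=50_000, r_max=6.0,
                                            bin_width=1.0, seed=5))
        occ = ~mc.empty_bins & ~ex.empty_bins
        z = np.abs(mc.values[occ] - ex.values[occ]) / mc.stderr[occ]
        assert np.all(z < 3.0)

    def test_deviation_shrinks_with_pair_count(self, blob_volume):
        vol, mask = blob_volume
        ex = ws2_exhaustive(vol, mask, r_max=6.0, bin_width=1.0)
        rms = {}
        for n in (10**3, 10**4, 10**5):
            mc = ws2_curve(vol, mask, WS2Config(n_pairs=n, r_max=6.0,
                                                bin_width=1.0, seed=5))
            occ = ~mc.empty_bins & ~ex.empty_bins
            rms[n] = float(np.sqrt(np.mean(
                (mc.values[occ] - ex.values[occ]) ** 2)))
        assert rms[10**5] < rms[10**3]
        # expected ~ sqrt(100) = 10x shrink; allow generous Monte-Carlo slack
        assert 3.0 < rms[10**3] / rms[10**5] < 40.0

    def test_pair_order_invariance(self, blob_volume):
        vol, mask = blob_volume
        cfg = WS2Config(n_pairs=5000, r_max=6.0, bin_width=1.0, seed=2)
        i1, i2, d = sample_pairs(mask, vol.spacing, cfg)
        fwd = ws2_from_pairs(vol, i1, i2, d, cfg)
        rev = ws2_from_pairs(vol, i2, i1, d, cfg)
        np.testing.assert_array_equal(fwd.values, rev.values)
        assert fwd.auc == rev.auc and fwd.slope == rev.slope

    def test_auc_linear_in_uniform_value(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        cfg = WS2Config(n_pairs=2000, r_max=4.0, bin_width=1.0, seed=0)
        auc1 = ws2_curve(_vol(np.full((8, 8, 8), 1.0)), mask, cfg).auc
        auc3 = ws2_curve(_vol(np.full((8, 8, 8), 3.0)), mask, cfg).auc
        assert auc3 == pytest.approx(3.0 * auc1, rel=1e-12)

    def test_empty_bins_flagged_and_interpolated(self):
        # 2 mm spacing: no pair can land in the [0,1) and [1,2) mm bins
        vol = _vol(np.full((8, 8, 8), 2.0), spacing=(2.0, 2.0, 2.0))
        mask = np.ones((8, 8, 8), dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            curve = ws2_curve(vol, mask, WS2Config(n_pairs=3000, seed=1))
        assert curve.empty_bins[:2].all()
        assert np.isnan(curve.values[:2]).all()
        np.testing.assert_allclose(curve.filled_values, 2.0, rtol=1e-12)

    def test_nan_voxels_are_excluded_from_sampling(self):
        data = np.full((8, 8, 8), 1.0)
        data[:4] = np.nan
        mask = np.ones((8, 8, 8), dtype=bool)
        curve = ws2_curve(_vol(data), mask,
                          WS2Config(n_pairs=1000, r_max=4.0, seed=0))
        assert np.isfinite(curve.auc)


class TestSubjectSeed:
    def test_deterministic_and_bounded(self):
        a = subject_seed(17, "sub01", "baseline")
        assert a == subject_seed(17, "sub01", "baseline")
        assert 0 <= a < 2**31

    def test_varies_with_each_component(self):
        base = subject_seed(17, "sub01", "baseline")
        assert base != subject_seed(18, "sub01", "baseline")
        assert base != subject_seed(17, "sub02", "baseline")
        assert base != subject_seed(17, "sub01", "followup")
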