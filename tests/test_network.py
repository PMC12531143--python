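import numpy as np
import pytest
from scipy import stats

from conftest import bh_stepup
from fcnm.network import (
    FCMap,
    GroupTMap,
    NetworkProbabilityMap,
    dice,
    fdr_binarize,
    fisher_z,
    group_onesample_t,
    overlap_probability,
    seed_fc_map,
    seed_timeseries,
    threshold_network,
)
from fcnm.volumes import BinaryMask, Volume3D, Volume4D


def vol4(rng, shape=(6, 6, 6), T=50):
    return Volume4D(rng.standard_normal((*shape, T)), np.eye(4))


def mask_at(shape, voxels):
    data = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        data[v] = 1
    return BinaryMask(data, np.eye(4))


def full_mask(shape):
    return BinaryMask(np.ones(shape, dtype=np.uint8), np.eye(4))


class TestSeedTimeseries:
    def test_single_voxel_seed_returns_that_series(self, rng):
        vol = vol4(rng)
        seed = mask_at(vol.shape[:3], [(2, 3, 1)])
        np.testing.assert_array_equal(seed_timeseries(vol, seed), vol.data[2, 3, 1])

    def test_mean_of_two_voxels(self, rng):
        vol = vol4(rng)
        seed = mask_at(vol.shape[:3], [(0, 0, 0), (1, 1, 1)])
        expected = (vol.data[0, 0, 0] + vol.data[1, 1, 1]) / 2
        np.testing.assert_allclose(seed_timeseries(vol, seed), expected)

    def test_empty_seed_rejected(self, rng):
        vol = vol4(rng)
        with pytest.raises(ValueError, match="empty seed"):
            seed_timeseries(vol, mask_at(vol.shape[:3], []))


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half(self):
        # 0.5 * ln(1.5 / 0.5)
        assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, 20)
        np.testing.assert_allclose(fisher_z(-r), -np.asarray(fisher_z(r)))

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestSeedFCMap:
    def test_self_correlated_voxel_hits_clip_bound(self, rng):
        vol = vol4(rng)
        seed = mask_at(vol.shape[:3], [(2, 2, 2)])
        fc = seed_fc_map(vol, seed, full_mask(vol.shape[:3]))
        z = fc.z_map.data[2, 2, 2]
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_anticorrelated_voxel_at_negative_bound(self, rng):
        vol = vol4(rng)
        vol.data[0, 0, 0] = -vol.data[3, 3, 3]
        seed = mask_at(vol.shape[:3], [(3, 3, 3)])
        fc = seed_fc_map(vol, seed, full_mask(vol.shape[:3]))
        assert fc.z_map.data[0, 0, 0] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_independent_noise_has_small_r(self, rng):
        vol = vol4(rng, T=200)
        seed = mask_at(vol.shape[:3], [(0, 0, 0)])
        fc = seed_fc_map(vol, seed, full_mask(vol.shape[:3]))
        r = np.tanh(fc.z_map.data[5, 5, 5])
        assert abs(r) < 0.2  # null |r| < 0.2 with probability ~0.995 at T=200

    def test_zero_variance_voxel_flagged(self, rng):
        vol = vol4(rng)
        vol.data[1, 1, 1] = 0.0
        seed = mask_at(vol.shape[:3], [(4, 4, 4)])
        fc = seed_fc_map(vol, seed, full_mask(vol.shape[:3]))
        assert fc.z_map.data[1, 1, 1] == 0.0
        assert fc.zero_variance_mask[1, 1, 1]


class TestGroupT:
    def _maps(self, values, shape=(2, 2, 2)):
        out = []
        for v in values:
            data = np.full(shape, float(v))
            out.append(FCMap(z_map=Volume3D(data, np.eye(4))))
        return out

    def test_hand_computed_t(self):
        tmap = group_onesample_t(self._maps([1.0, 2.0, 3.0]))
        assert tmap.df == 2
        assert tmap.t_map.data[0, 0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-9)

    def test_symmetric_values_give_zero_t(self):
        tmap = group_onesample_t(self._maps([-1.0, 1.0]))
        assert tmap.t_map.data[0, 0, 0] == 0.0

    def test_degenerate_equal_values_hit_sentinel(self):
        tmap = group_onesample_t(self._maps([2.0, 2.0, 2.0]))
        assert np.isposinf(tmap.t_map.data[0, 0, 0])
        assert tmap.p_map.data[0, 0, 0] == 0.0
        assert tmap.degenerate_mask.all()

    def test_agrees_with_reference_implementation(self, rng):
        stack = rng.standard_normal((8, 3, 3, 3))
        maps = [FCMap(z_map=Volume3D(s, np.eye(4))) for s in stack]
        tmap = group_onesample_t(maps)
        ref_t, ref_p = stats.ttest_1samp(stack, 0.0, axis=0)
        np.testing.assert_allclose(tmap.t_map.data, ref_t, atol=1e-10)
        np.testing.assert_allclose(tmap.p_map.data, ref_p, atol=1e-10)


class TestFDRBinarize:
    def _tmap(self, p_values, t_values, shape):
        p = np.asarray(p_values, dtype=float).reshape(shape)
        t = np.asarray(t_values, dtype=float).reshape(shape)
        return GroupTMap(
            t_map=Volume3D(t, np.eye(4)), df=10, p_map=Volume3D(p, np.eye(4))
        )

    def test_bh_worked_example_all_rejected(self):
        # largest k with p_(k) <= k*0.05/3 is k=3
        tmap = self._tmap([0.01, 0.02, 0.04], [3, 3, 3], (3, 1, 1))
        out = fdr_binarize(tmap, q=0.05)
        assert out.n_voxels == 3

    def test_all_p_one_gives_empty_mask(self):
        tmap = self._tmap([1.0] * 8, [1.0] * 8, (2, 2, 2))
        assert fdr_binarize(tmap).n_voxels == 0

    def test_negative_t_excluded_when_positive_only(self):
        tmap = self._tmap([0.001, 0.001], [2.0, -2.0], (2, 1, 1))
        out = fdr_binarize(tmap, positive_only=True)
        assert out.data[0, 0, 0] == 1
        assert out.data[1, 0, 0] == 0
        both = fdr_binarize(tmap, positive_only=False)
        assert both.n_voxels == 2

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(25):
            m = int(rng.integers(3, 200))
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            tmap = self._tmap(p, np.ones(m), (m, 1, 1))
            ours = fdr_binarize(tmap, q=0.05).data.reshape(-1).astype(bool)
            np.testing.assert_array_equal(ours, bh_stepup(p, 0.05))

    def test_family_restricted_to_analysis_mask(self):
        p = np.array([0.04, 0.04, 0.04, 0.9]).reshape(4, 1, 1)
        tmap = self._tmap(p, np.ones((4, 1, 1)), (4, 1, 1))
        sub = mask_at((4, 1, 1), [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        # within the 3-voxel family all p=0.04 survive; the excluded voxel
        # stays 0 regardless
        out = fdr_binarize(tmap, q=0.05, analysis_mask=sub)
        assert out.n_voxels == 3
        assert out.data[3, 0, 0] == 0


class TestOverlap:
    def test_counting(self):
        shape = (2, 2, 1)
        maps = [
            mask_at(shape, [(0, 0, 0)]),
            mask_at(shape, [(0, 0, 0)]),
            mask_at(shape, [(1, 1, 0)]),
            mask_at(shape, []),
        ]
        prob = overlap_probability(maps)
        assert prob.k_contrasts == 4
        assert prob.prob.data[0, 0, 0] == pytest.approx(0.5)
        assert prob.prob.data[1, 1, 0] == pytest.approx(0.25)

    def test_all_empty_gives_zero_map(self):
        prob = overlap_probability([mask_at((2, 2, 2), []) for _ in range(3)])
        assert prob.prob.data.sum() == 0

    def test_single_map_identity(self):
        m = mask_at((3, 3, 3), [(1, 1, 1)])
        prob = overlap_probability([m])
        np.testing.assert_array_equal(prob.prob.data, m.data)

    def test_prob_times_k_integral(self, rng):
        maps = [
            BinaryMask((rng.uniform(size=(4, 4, 4)) > 0.5).astype(np.uint8), np.eye(4))
            for _ in range(7)
        ]
        prob = overlap_probability(maps)
        scaled = prob.prob.data * prob.k_contrasts
        np.testing.assert_allclose(scaled, np.rint(scaled), atol=1e-9)


class TestThreshold:
    def _prob(self, values):
        data = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        return NetworkProbabilityMap(prob=Volume3D(data, np.eye(4)), k_contrasts=4)

    def test_exactly_half_included(self):
        net = threshold_network(self._prob([0.5, 0.25]), 0.5)
        assert net.mask.data[0, 0, 0] == 1
        assert net.mask.data[1, 0, 0] == 0

    def test_nesting_in_tau(self):
        prob = self._prob([0.25, 0.5, 0.75, 1.0])
        loose = threshold_network(prob, 0.5).mask.data
        tight = threshold_network(prob, 0.75).mask.data
        assert np.all(tight <= loose)

    def test_tau_above_max_gives_empty(self):
        assert threshold_network(self._prob([0.25, 0.5]), 0.75).mask.n_voxels == 0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            threshold_network(self._prob([0.5]), 0.0)


class TestDice:
    def test_identical_masks(self):
        m = mask_at((3, 3, 3), [(0, 0, 0), (1, 1, 1)])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = mask_at((3, 3, 3), [(0, 0, 0)])
        b = mask_at((3, 3, 3), [(2, 2, 2)])
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = mask_at((3, 3, 3), [(0, 0, 0), (1, 1, 1)])
        b = mask_at((3, 3, 3), [(0, 0, 0)])
        assert dice(a, b) == pytest.approx(2 / 3)
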