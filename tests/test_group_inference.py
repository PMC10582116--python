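"""TFCE transform and max-statistic permutation inference."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from skimage import measure

from motormap.core import StatMap
from motormap.group_inference import (
    GroupPermResult,
    TfceParams,
    permutation_one_sample,
    permutation_two_sample,
    tfce_transform,
    threshold_map,
)


def tfce_oracle(data, params):
    """Brute-force TFCE: relabel connected components independently at every
    threshold with scikit-image and accumulate extent^E * h^H * dh."""
    conn = {6: 1, 18: 2, 26: 3}[params.connectivity]
    h_max = max(data.max(), 0.0)
    out = np.zeros_like(data, dtype=float)
    if h_max <= 0:
        return out
    dh = h_max / params.n_steps
    for h in np.linspace(dh, h_max, params.n_steps):
        labels = measure.label(data >= h, connectivity=conn)
        for region in measure.regionprops(labels):
            contrib = region.area**params.extent_exponent * h**params.height_exponent * dh
            for x, y, z in region.coords:
                out[x, y, z] += contrib
    return out


class TestTfce:
    def test_all_zero_map_maps_to_zero(self):
        out = tfce_transform(StatMap(np.zeros((6, 6, 6))))
        assert np.all(out.data == 0.0)

    def test_single_voxel_closed_form(self):
        # isolated voxel of height 2: TFCE -> integral of h^2 dh on (0,2] = 8/3
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 2.0
        out = tfce_transform(StatMap(data), TfceParams(n_steps=1000))
        assert out.data[4, 4, 4] == pytest.approx(8 / 3, rel=0.01)

    def test_matches_per_threshold_relabeling_oracle(self, rng):
        # two smooth blobs plus noise on a 10^3 grid
        data = rng.normal(0, 0.3, (10, 10, 10))
        xx, yy, zz = np.mgrid[0:10, 0:10, 0:10]
        data += 3.0 * np.exp(-((xx - 3) ** 2 + (yy - 3) ** 2 + (zz - 5) ** 2) / 4)
        data += 2.0 * np.exp(-((xx - 7) ** 2 + (yy - 7) ** 2 + (zz - 5) ** 2) / 3)
        params = TfceParams(n_steps=100)
        ours = tfce_transform(StatMap(data), params).data
        oracle = tfce_oracle(data, params) - tfce_oracle(-data, params)
        denom = np.abs(oracle).max()
        assert np.abs(ours - oracle).max() / denom < 0.005

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_oracle_agreement_across_connectivities(self, rng, connectivity):
        data = rng.normal(0, 1, (8, 8, 8))
        params = TfceParams(n_steps=50, connectivity=connectivity)
        ours = tfce_transform(StatMap(data), params).data
        oracle = tfce_oracle(data, params) - tfce_oracle(-data, params)
        np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_scale_law(self, rng):
        # TFCE(c * map) ~ c^(H+1) * TFCE(map): dh scales with the max, so the
        # discretized sum scales exactly
        data = rng.normal(0, 1, (8, 8, 8))
        params = TfceParams(n_steps=1000)
        base = tfce_transform(StatMap(data), params).data
        scaled = tfce_transform(StatMap(2.5 * data), params).data
        np.testing.assert_allclose(scaled, 2.5**3 * base, rtol=1e-8)

    def test_raising_a_voxel_never_decreases_its_score(self, rng):
        data = rng.normal(0, 1, (6, 6, 6))
        params = TfceParams(n_steps=200)
        base = tfce_transform(StatMap(data), params).data
        for _ in range(5):
            idx = tuple(rng.integers(0, 6, 3))
            bumped = data.copy()
            bumped[idx] += rng.uniform(0.1, 2.0)
            out = tfce_transform(StatMap(bumped), params).data
            assert out[idx] >= base[idx] - 1e-9

    def test_non_finite_map_rejected(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            tfce_transform(StatMap(data))


def blob_maps(n, value=1.0, shape=(6, 6, 6)):
    data = np.zeros(shape)
    data[2:4, 2:4, 2:4] = value
    return [StatMap(data.copy()) for _ in range(n)]


class TestOneSample:
    def test_identical_positive_maps_reach_minimal_p(self):
        n = 6
        res = permutation_one_sample(blob_maps(n), TfceParams(n_steps=20), n_perm=200)
        assert res.exhaustive and res.n_perm == 2**n
        blob = blob_maps(1)[0].data > 0
        # only the identity sign-flip attains the observed maximum
        np.testing.assert_allclose(res.fwe_p.data[blob], 1 / 2**n)

    def test_antisymmetric_pairs_give_null_result(self, rng):
        m = rng.normal(0, 1, (5, 5, 5))
        m2 = rng.normal(0, 1, (5, 5, 5))
        maps = [StatMap(m), StatMap(-m), StatMap(m2), StatMap(-m2)]
        res = permutation_one_sample(maps, TfceParams(n_steps=20), n_perm=100)
        assert np.all(res.observed_stat.data == 0.0)
        assert np.all(res.fwe_p.data == 1.0)

    def test_exhaustive_matches_manual_sign_flip_enumeration(self, rng):
        # scalar "maps": one voxel, n=5 -> p from all 32 sign flips
        vals = rng.normal(0.8, 1.0, 5)
        maps = [StatMap(np.full((1, 1, 1), v)) for v in vals]
        params = TfceParams(n_steps=10)
        res = permutation_one_sample(maps, params, n_perm=100)
        obs_t = sps.ttest_1samp(vals, 0.0).statistic
        count = 0
        for signs in itertools.product([1, -1], repeat=5):
            t = sps.ttest_1samp(np.array(signs) * vals, 0.0).statistic
            if max(t, 0.0) >= max(obs_t, 0.0) - 1e-12:
                count += 1
        # single voxel: TFCE is monotone in t, so the max-statistic p reduces
        # to the sign-flip p of t itself
        assert res.fwe_p.data[0, 0, 0] == pytest.approx(count / 32)

    def test_seeded_runs_are_bit_identical(self, rng):
        maps = [StatMap(rng.normal(0.5, 1, (6, 6, 6))) for _ in range(12)]
        r1 = permutation_one_sample(maps, TfceParams(n_steps=10), n_perm=50, seed=9)
        r2 = permutation_one_sample(maps, TfceParams(n_steps=10), n_perm=50, seed=9)
        assert np.array_equal(r1.fwe_p.data, r2.fwe_p.data)
        assert np.array_equal(r1.null_max, r2.null_max)


class TestTwoSample:
    def test_identical_groups_reject_nowhere(self, rng):
        maps = [StatMap(rng.normal(0, 1, (5, 5, 5))) for _ in range(4)]
        res = permutation_two_sample(maps, maps, TfceParams(n_steps=10), n_perm=100)
        assert np.all(res.observed_stat.data == 0.0)
        assert not threshold_map(res, 0.05).data.any()

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 4)])
    def test_single_voxel_matches_exhaustive_label_enumeration(self, rng, na, nb):
        a = rng.normal(1.0, 1.0, na)
        b = rng.normal(0.0, 1.0, nb)
        maps_a = [StatMap(np.full((1, 1, 1), v)) for v in a]
        maps_b = [StatMap(np.full((1, 1, 1), v)) for v in b]
        res = permutation_two_sample(
            maps_a, maps_b, TfceParams(n_steps=10), n_perm=1000, direction="a_gt_b"
        )
        pool = np.concatenate([a, b])
        obs = sps.ttest_ind(a, b).statistic
        count, total = 0, 0
        for a_idx in itertools.combinations(range(na + nb), na):
            b_idx = [i for i in range(na + nb) if i not in a_idx]
            t = sps.ttest_ind(pool[list(a_idx)], pool[b_idx]).statistic
            if max(t, 0.0) >= max(obs, 0.0) - 1e-12:
                count += 1
            total += 1
        assert res.exhaustive and res.n_perm == total
        assert res.fwe_p.data[0, 0, 0] == pytest.approx(count / total)

    def test_direction_flip_negates_observed_stat(self, rng):
        maps_a = [StatMap(rng.normal(1, 1, (4, 4, 4))) for _ in range(3)]
        maps_b = [StatMap(rng.normal(0, 1, (4, 4, 4))) for _ in range(3)]
        r_ab = permutation_two_sample(maps_a, maps_b, TfceParams(n_steps=5), 50, 0, "a_gt_b")
        r_ba = permutation_two_sample(maps_a, maps_b, TfceParams(n_steps=5), 50, 0, "b_gt_a")
        np.testing.assert_allclose(r_ab.observed_stat.data, -r_ba.observed_stat.data)

    def test_small_group_rejected(self, rng):
        maps = [StatMap(rng.normal(0, 1, (4, 4, 4))) for _ in range(3)]
        with pytest.raises(ValueError):
            permutation_two_sample(maps[:1], maps, n_perm=10)


class TestThresholdMap:
    def make_result(self, p_values):
        p = np.asarray(p_values, dtype=float)
        sm = StatMap(p)
        return GroupPermResult(sm, sm, np.array([1.0]), sm, n_perm=1, seed=None)

    def test_all_p_one_gives_empty_mask(self):
        res = self.make_result(np.ones((4, 4, 4)))
        assert threshold_map(res, 0.05).data.sum() == 0

    def test_alpha_one_gives_full_mask(self):
        res = self.make_result(np.ones((4, 4, 4)))
        assert threshold_map(res, 1.0).data.sum() == 64

    def test_count_matches_brute_force(self, rng):
        p = rng.uniform(0, 1, (6, 6, 6))
        res = self.make_result(p)
        assert threshold_map(res, 0.05).data.sum() == (p <= 0.05).sum()
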