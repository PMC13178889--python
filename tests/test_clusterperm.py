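"""Pointwise t-maps, cluster forming, permutation null, corrected p-values."""

import warnings
from collections import deque

import numpy as np
import pytest
from scipy import stats

from pedoperm.clusterperm import (
    PermConfig,
    StatMap,
    cluster_test,
    form_clusters,
    permutation_null,
    pointwise_tmap,
)

CFG = PermConfig(min_group_coverage=0.0, seed=0)


class TestPointwiseTmap:
    def test_null_groups_give_zero_t(self):
        a = np.tile([[1.0, 2.0, 3.0]], (4, 1)).T + np.arange(3)[:, None] * 0
        a = np.stack([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        b = np.stack([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        sm = pointwise_tmap(a, b, CFG)
        np.testing.assert_allclose(sm.t_values, 0.0)

    def test_matches_scipy_welch_per_pixel(self, rng):
        a = rng.normal(0, 1, (8, 5))
        b = rng.normal(0.5, 2, (6, 5))
        sm = pointwise_tmap(a, b, CFG)
        t_ref, p_ref = stats.ttest_ind(a, b, axis=0, equal_var=False)
        np.testing.assert_allclose(sm.t_values, t_ref, rtol=1e-10)
        np.testing.assert_allclose(sm.p_values, p_ref, rtol=1e-10)

    def test_swapping_groups_negates_map(self, rng):
        a = rng.normal(0, 1, (6, 4, 4))
        b = rng.normal(1, 1, (5, 4, 4))
        t1 = pointwise_tmap(a, b, CFG).t_values
        t2 = pointwise_tmap(b, a, CFG).t_values
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_coverage_rule_masks_sparse_pixels(self, rng):
        a = np.abs(rng.normal(1, 0.2, (10, 3)))
        b = np.abs(rng.normal(1, 0.2, (10, 3)))
        a[:, 1] = 0.0  # absent in group a
        b[:6, 2] = 0.0  # 40% coverage in group b
        sm = pointwise_tmap(a, b, PermConfig(min_group_coverage=0.5))
        np.testing.assert_array_equal(sm.testable_mask, [True, False, False])

    def test_zero_variance_pixel_warns_and_zeroes(self):
        a = np.ones((3, 2))
        b = np.ones((3, 2))
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            sm = pointwise_tmap(a, b, CFG)
        assert sm.n_zero_variance == 2
        assert (sm.t_values == 0).all() and (sm.p_values == 1).all()


def _bfs_clusters(mask, connectivity=8):
    """Independent flood-fill oracle for contiguity."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:
        offs = [(-1,), (1,)]
    elif connectivity == 8:
        offs = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    out = []
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        comp = set()
        q = deque([idx])
        seen[idx] = True
        while q:
            cur = q.popleft()
            comp.add(cur)
            for off in offs:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nxt, mask.shape)) and mask[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    q.append(nxt)
        out.append(frozenset(comp))
    return set(out)


class TestFormClusters:
    def _statmap(self, t):
        t = np.asarray(t, dtype=float)
        p = np.where(np.abs(t) > 3, 1e-4, 1.0)
        return StatMap(
            t_values=t, p_values=p, df=np.full(t.shape, 10.0),
            testable_mask=np.ones(t.shape, bool),
        )

    def test_no_superthreshold_points_empty(self):
        assert form_clusters(self._statmap(np.zeros((4, 4)))) == []

    def test_singleton_cluster(self):
        t = np.zeros((5, 5))
        t[2, 2] = 4.5
        c, = form_clusters(self._statmap(t))
        assert c.size == 1 and c.sign == "positive"
        assert c.mass == pytest.approx(4.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_memberships_match_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.where(rng.random((12, 9)) < 0.3, 5.0, 0.0)
        t *= np.where(rng.random((12, 9)) < 0.5, 1, -1)
        clusters = form_clusters(self._statmap(t))
        got = {frozenset(zip(*np.nonzero(c.members))) for c in clusters}
        want = _bfs_clusters(t > 3) | _bfs_clusters(t < -3)
        assert got == want

    def test_1d_adjacency(self):
        t = np.array([0.0, 4.0, 4.0, 0.0, -4.0, 0, 4.0])
        clusters = form_clusters(self._statmap(t))
        sizes = sorted((c.size, c.sign) for c in clusters)
        assert sizes == [(1, "negative"), (1, "positive"), (2, "positive")]

    def test_opposite_signs_not_joined(self):
        t = np.array([[4.0, -4.0, 4.0]])
        assert len(form_clusters(self._statmap(t))) == 3


class TestPermutationNull:
    def test_same_seed_identical_null(self, rng):
        a = rng.normal(0, 1, (10, 6))
        b = rng.normal(0, 1, (9, 6))
        cfg = PermConfig(n_perm=50, min_group_coverage=0, seed=3, exhaustive=False)
        n1, _ = permutation_null(a, b, cfg)
        n2, _ = permutation_null(a, b, cfg)
        np.testing.assert_array_equal(n1, n2)

    def test_exhaustive_enumeration_on_tiny_input(self, rng):
        a = rng.normal(1, 1, (5, 8))
        b = rng.normal(0, 1, (3, 8))
        null, exhaustive = permutation_null(a, b, PermConfig(n_perm=1000, min_group_coverage=0))
        assert exhaustive and len(null) == 56

    def test_forced_sampling_warns_when_undersized(self, rng):
        a = rng.normal(0, 1, (3, 4))
        b = rng.normal(0, 1, (2, 4))
        cfg = PermConfig(n_perm=100, min_group_coverage=0, seed=1, exhaustive=False)
        with pytest.warns(UserWarning, match="distinct relabelings"):
            null, exhaustive = permutation_null(a, b, cfg)
        assert not exhaustive and len(null) == 100


class TestClusterTest:
    def test_p_corrected_floor_and_flag(self, rng):
        a = rng.normal(3, 1, (12, 10))
        b = rng.normal(0, 1, (12, 10))
        cfg = PermConfig(n_perm=99, min_group_coverage=0, seed=5, exhaustive=False)
        res = cluster_test(a, b, cfg)
        top = res.clusters[0]
        assert top.significant and top.p_corrected >= 1 / 100
        assert all(c.p_corrected <= 1.0 for c in res.clusters)

    def test_monotone_mass_in_effect_size(self, rng):
        noise_a = rng.normal(0, 1, (10, 6, 6))
        noise_b = rng.normal(0, 1, (10, 6, 6))
        masses = []
        for delta in (0.8, 1.6, 3.2):
            a = noise_a.copy()
            a[:, 2:5, 2:5] += delta
            sm = pointwise_tmap(a, noise_b, CFG)
            clusters = form_clusters(sm, CFG)
            masses.append(max((c.mass for c in clusters), default=0.0))
        assert masses == sorted(masses)

    def test_subject_order_invariance_exhaustive(self, rng):
        a = rng.normal(0.5, 1, (5, 7))
        b = rng.normal(0, 1, (4, 7))
        cfg = PermConfig(n_perm=200, min_group_coverage=0)
        res1 = cluster_test(a, b, cfg)
        perm = rng.permutation(5)
        res2 = cluster_test(a[perm], b, cfg)
        np.testing.assert_allclose(
            np.sort(res1.null_distribution), np.sort(res2.null_distribution)
        )
        assert [c.p_corrected for c in res1.clusters] == [
            c.p_corrected for c in res2.clusters
        ]

    def test_applies_to_1d_series(self, rng):
        a = rng.normal(0, 1, (15, 50))
        a[:, 20:30] += 2.0
        b = rng.normal(0, 1, (15, 50))
        res = cluster_test(a, b, PermConfig(n_perm=200, min_group_coverage=0, seed=2))
        sig = res.significant_mask()
        assert sig[22:28].all()
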