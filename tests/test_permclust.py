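"""Cluster-mass permutation inference tests."""

import numpy as np
import pytest
from scipy import stats as sps

from srcflow import permclust
from srcflow.permclust import (
    PermutationConfig,
    _batched_tmaps,
    _kth_largest_per_group,
    _perm_label_matrix,
    cluster_masses,
    correct_clusters,
    group_cluster_inference,
    permutation_null,
    pixelwise_tmap,
    stack_edge_data,
    threshold_mask,
)


# ---------------------------------------------------------------------------
# pixel statistics
# ---------------------------------------------------------------------------


class TestPixelStats:
    def test_matches_scipy(self, rng):
        a = rng.standard_normal((9, 4, 6))
        b = rng.standard_normal((12, 4, 6)) + 0.3
        t, df = pixelwise_tmap(a, b)
        assert df == 19
        ref = sps.ttest_ind(a, b, axis=0, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)

    def test_antisymmetry(self, rng):
        a = rng.standard_normal((6, 3, 3))
        b = rng.standard_normal((7, 3, 3))
        t1, _ = pixelwise_tmap(a, b)
        t2, _ = pixelwise_tmap(b, a)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_zero_variance_nan(self):
        a = np.ones((4, 2, 2))
        b = np.ones((5, 2, 2))
        t, _ = pixelwise_tmap(a, b)
        assert np.all(np.isnan(t))

    def test_threshold_strict(self):
        df = 20
        t_crit = sps.t.ppf(0.995, df)
        t = np.array([[t_crit, t_crit + 1e-9, -t_crit, np.nan]])
        m = threshold_mask(t, df, 0.01)
        np.testing.assert_array_equal(m, [[False, True, False, False]])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _flood_fill_reference(mask, t_map, connectivity):
    """Slow reference clustering: BFS flood fill, sign-pure."""
    F, T = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    out = []
    for i in range(F):
        for j in range(T):
            if not mask[i, j] or seen[i, j]:
                continue
            sign = np.sign(t_map[i, j])
            stack = [(i, j)]
            seen[i, j] = True
            members = []
            while stack:
                ci, cj = stack.pop()
                members.append((ci, cj))
                for di, dj in nbrs:
                    ni, nj = ci + di, cj + dj
                    if (
                        0 <= ni < F
                        and 0 <= nj < T
                        and mask[ni, nj]
                        and not seen[ni, nj]
                        and np.sign(t_map[ni, nj]) == sign
                    ):
                        seen[ni, nj] = True
                        stack.append((ni, nj))
            out.append(
                (frozenset(members), sum(t_map[m] for m in members), int(sign))
            )
    return out


class TestClustering:
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill(self, rng, connectivity):
        for _ in range(5):
            t = rng.standard_normal((8, 12)) * 3
            mask = np.abs(t) > 2.0
            got = cluster_masses(mask, t, connectivity)
            ref = _flood_fill_reference(mask, t, connectivity)
            got_set = {
                (frozenset(zip(*np.nonzero(c.pixels))), c.sign) for c in got
            }
            ref_set = {(m, s) for m, _, s in ref}
            assert got_set == ref_set
            ref_masses = sorted(m for _, m, _ in ref)
            got_masses = sorted(c.mass for c in got)
            np.testing.assert_allclose(got_masses, ref_masses, atol=1e-12)

    def test_sign_purity_splits_touching_clusters(self):
        t = np.array([[3.0, -3.0, 3.0]])
        mask = np.abs(t) > 2
        cl = cluster_masses(mask, t, 4)
        assert len(cl) == 3
        assert sorted(c.sign for c in cl) == [-1, 1, 1]

    def test_diagonal_connectivity(self):
        t = np.zeros((3, 3))
        t[0, 0] = t[1, 1] = 3.0
        mask = t > 2
        assert len(cluster_masses(mask, t, 4)) == 2
        assert len(cluster_masses(mask, t, 8)) == 1


# ---------------------------------------------------------------------------
# batched engine internals
# ---------------------------------------------------------------------------


class TestBatchedEngine:
    def test_tmaps_match_reference(self, rng):
        X = rng.standard_normal((14, 40))
        perm = _perm_label_matrix(np.r_[np.ones(6, bool), np.zeros(8, bool)], 25, 0)
        t, df = _batched_tmaps(X, perm)
        for p in range(25):
            ref = sps.ttest_ind(X[perm[p]], X[~perm[p]], axis=0, equal_var=True)
            np.testing.assert_allclose(t[p], ref.statistic, atol=1e-10)
        assert np.all(df == 12)

    def test_perm_label_matrix_properties(self):
        labels = np.r_[np.ones(5, bool), np.zeros(7, bool)]
        P = _perm_label_matrix(labels, 200, seed=3)
        assert P.shape == (200, 12)
        np.testing.assert_array_equal(P.sum(axis=1), 5)
        # deterministic
        np.testing.assert_array_equal(P, _perm_label_matrix(labels, 200, seed=3))

    def test_warns_on_few_relabelings(self):
        labels = np.array([True, True, False, False])
        with pytest.warns(UserWarning, match="distinct relabelings"):
            _perm_label_matrix(labels, 100, seed=0)

    def test_kth_largest_per_group(self):
        groups = np.array([0, 0, 0, 2, 2])
        values = np.array([5.0, 9.0, 1.0, 4.0, 7.0])
        out1 = _kth_largest_per_group(groups, values, 3, 1)
        np.testing.assert_allclose(out1, [9.0, 0.0, 7.0])
        out2 = _kth_largest_per_group(groups, values, 3, 2)
        np.testing.assert_allclose(out2, [5.0, 0.0, 4.0])
        out3 = _kth_largest_per_group(groups, values, 3, 3)
        np.testing.assert_allclose(out3, [1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# null construction and correction
# ---------------------------------------------------------------------------


class TestNull:
    def test_deterministic(self, rng):
        data = rng.standard_normal((12, 3, 5, 8))
        ga = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        cfg = PermutationConfig(n_perm=150, seed=42)
        n1 = permutation_null(data, ga, cfg)
        n2 = permutation_null(data, ga, cfg)
        np.testing.assert_array_equal(n1["pos"], n2["pos"])
        np.testing.assert_array_equal(n1["neg"], n2["neg"])

    def test_pooled_nulls_match_signs(self, rng):
        data = rng.standard_normal((12, 3, 5, 8))
        ga = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        n = permutation_null(data, ga, PermutationConfig(n_perm=120, seed=1))
        np.testing.assert_array_equal(n["pos"], n["neg"])

    def test_across_edge_uses_second_largest(self, rng):
        """With u=1 the across-edge null is below the per-iteration maximum."""
        data = rng.standard_normal((16, 4, 6, 10))
        ga = np.r_[np.ones(8, bool), np.zeros(8, bool)]
        cfg1 = PermutationConfig(n_perm=150, seed=5, u=1)
        cfg0 = PermutationConfig(n_perm=150, seed=5, u=0)
        n1 = permutation_null(data, ga, cfg1)
        n0 = permutation_null(data, ga, cfg0)
        assert np.all(n1["pos"] <= n0["pos"])
        assert np.any(n1["pos"] < n0["pos"])

    def test_within_edge_requires_single_edge(self, rng):
        data = rng.standard_normal((8, 2, 3, 4))
        ga = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        cfg = PermutationConfig(n_perm=100, scope="within_edge")
        with pytest.raises(ValueError, match="single edge"):
            permutation_null(data, ga, cfg)

    def test_correct_clusters_add_one(self):
        null = {"pos": np.array([1.0, 2.0, 3.0, 4.0]), "neg": np.array([5.0] * 4)}
        cl = cluster_masses(
            np.array([[True]]), np.array([[3.5]]), 4
        )
        correct_clusters(cl, null, alpha_cluster=0.5)
        # masses >= 3.5 in null: {4.0} -> p = (1+1)/(1+4)
        assert cl[0].p_value == pytest.approx(2 / 5)
        assert cl[0].significant

    def test_p_value_floor(self, rng):
        data = rng.standard_normal((10, 1, 4, 4))
        data[:5] += 10.0  # overwhelming effect
        ga = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        cfg = PermutationConfig(n_perm=100, seed=0)
        res = group_cluster_inference(data, ga, cfg=cfg)
        for c in res[0].clusters:
            assert c.p_value >= 1.0 / 101.0


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            PermutationConfig(alpha_pixel=0.0)
        with pytest.raises(ValueError):
            PermutationConfig(n_perm=10)
        with pytest.raises(ValueError):
            PermutationConfig(scope="everywhere")
        with pytest.raises(ValueError):
            PermutationConfig(connectivity=6)
        with pytest.raises(ValueError):
            PermutationConfig(sign_mode="both")


class TestEndToEndInference:
    def test_planted_difference_detected(self, rng):
        n = 24
        data = rng.standard_normal((n, 2, 8, 12))
        ga = np.r_[np.ones(12, bool), np.zeros(12, bool)]
        # strong localized effect on edge 0 only
        data[ga, 0, 2:5, 3:8] += 2.5
        cfg = PermutationConfig(n_perm=300, seed=7)
        res = group_cluster_inference(data, ga, edges=["e0", "e1"], cfg=cfg)
        by_edge = {r.edge: r for r in res}
        assert len(by_edge["e0"].significant_clusters) >= 1
        big = max(by_edge["e0"].significant_clusters, key=lambda c: abs(c.mass))
        assert big.sign == 1
        # the planted block is inside the detected cluster's bounding box
        fi, ti = np.nonzero(big.pixels)
        assert fi.min() <= 2 and fi.max() >= 4
        assert ti.min() <= 3 and ti.max() >= 7
        assert len(by_edge["e1"].significant_clusters) == 0

    def test_label_swap_flips_sign(self, rng):
        data = rng.standard_normal((16, 1, 5, 6))
        ga = np.r_[np.ones(8, bool), np.zeros(8, bool)]
        data[ga, 0, 1:4, 1:4] += 2.0
        cfg = PermutationConfig(n_perm=200, seed=1)
        r1 = group_cluster_inference(data, ga, cfg=cfg)[0]
        r2 = group_cluster_inference(data, ~ga, cfg=cfg)[0]
        np.testing.assert_allclose(r1.t_map, -r2.t_map, atol=1e-10)

    def test_sparse_edges_skipped(self, rng):
        data = rng.standard_normal((10, 2, 3, 4))
        data[2:, 1] = np.nan  # edge 1: only 2 subjects, one per group
        ga = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        cfg = PermutationConfig(n_perm=100, seed=0)
        res = group_cluster_inference(data, ga, edges=["a", "b"], cfg=cfg)
        assert [r.edge for r in res] == ["a"]

    def test_stack_edge_data(self, tiny_parcellation, rng):
        from srcflow import density, mvar

        vals = rng.uniform(1, 4, (2, 2, 3, 4))
        vals[0, 0] = vals[1, 1] = np.nan
        W = np.zeros((2, 12))
        W[0, 0] = W[1, 5] = 1.0
        tens = density.project_to_roi(
            mvar.IcConnectivityTensor(
                values=vals,
                freqs=np.arange(3.0),
                times=np.arange(4.0),
                subject_id="s",
            ),
            W,
        )
        out = stack_edge_data([tens], [(0, 5), (5, 0), (1, 2)])
        np.testing.assert_allclose(out[0, 0], vals[0, 1])
        np.testing.assert_allclose(out[0, 1], vals[1, 0])
        assert np.all(np.isnan(out[0, 2]))


class TestFalsePositiveSmoke:
    def test_global_null_rarely_rejects(self):
        """Quick check (20 replicates) that pooled u-FWER is not broken.

        The full 200-replicate calibration lives in the acceptance tests.
        """
        n_false = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            data = rng.standard_normal((16, 6, 8, 15))
            ga = np.r_[np.ones(8, bool), np.zeros(8, bool)]
            cfg = PermutationConfig(n_perm=250, seed=rep)
            res = group_cluster_inference(data, ga, cfg=cfg)
            n_sig = sum(len(r.significant_clusters) for r in res)
            if n_sig > cfg.u:
                n_false += 1
        assert n_false <= 4  # ~0.05 nominal; generous bound for 20 reps
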