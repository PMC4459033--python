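"""Group statistics: t-maps, cluster permutation machinery, correlations,
FDR, and Fisher z comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from phasealign import (bh_fdr, cluster_size_permutation, fisher_z_compare,
                        pearson_r, pointwise_t_map)


class TestPointwiseTMap:
    def test_identical_conditions_degenerate(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 3, 4))
        t, p = pointwise_t_map(a, a.copy())
        assert np.all(t == 0.0) and np.all(p == 1.0)

    def test_hand_computed_paired_t(self):
        # paired differences (0.1, 0.2, 0.3): t = 0.2 / (0.1/sqrt(3))
        base = np.zeros((3, 1, 1))
        se = base + np.array([0.1, 0.2, 0.3]).reshape(3, 1, 1)
        t, p = pointwise_t_map(se, base)
        assert t[0, 0] == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-4)
        assert p[0, 0] == pytest.approx(
            2 * sps.t.sf(3.4641, df=2), rel=1e-3)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(1)
        a = rng.random((7, 100, 150))
        b = rng.random((7, 100, 150))
        _, p = pointwise_t_map(a, b)
        frac = np.mean(p < 0.05)
        # binomial fluctuation around 0.05 over 15000 points
        assert 0.04 < frac < 0.06

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="participants"):
            pointwise_t_map(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))


class TestClusterPermutation:
    def test_no_significant_points_no_clusters(self):
        rng = np.random.default_rng(2)
        base = rng.random((6, 4, 5))
        res = cluster_size_permutation(base + 1e-9 * rng.random((6, 4, 5)),
                                       base, n_permutations=200, seed=0)
        # essentially identical conditions: no (or only tiny, insignificant)
        # clusters, and never a significant one
        assert all(c.p_value > 0.05 for c in res.clusters)

    def test_strong_effect_found_and_localised(self):
        rng = np.random.default_rng(3)
        se = rng.normal(0.2, 0.02, (7, 10, 12))
        ue = rng.normal(0.2, 0.02, (7, 10, 12))
        se[:, 3:6, 4:8] += 0.3
        res = cluster_size_permutation(se, ue, n_permutations=500, seed=1)
        sig = [c for c in res.clusters if c.p_value < 0.05]
        assert len(sig) >= 1
        big = max(sig, key=lambda c: c.size)
        assert big.sign == 1
        f_idx = big.points[:, 0]
        assert f_idx.min() >= 3 and f_idx.max() <= 5

    def test_null_max_sizes_shape_and_p_range(self):
        rng = np.random.default_rng(4)
        res = cluster_size_permutation(rng.random((5, 6, 6)),
                                       rng.random((5, 6, 6)),
                                       n_permutations=150, seed=2)
        assert res.null_max_sizes.shape == (150,)
        for c in res.clusters:
            assert 0.0 < c.p_value <= 1.0

    def test_four_adjacency_no_diagonals(self):
        """Two suprathreshold points touching only diagonally form two
        clusters, not one."""
        se = np.zeros((8, 4, 4))
        se[:, 0, 0] = 0.5 + 0.01 * np.arange(8)
        se[:, 1, 1] = 0.5 + 0.01 * np.arange(8)
        res = cluster_size_permutation(se, np.zeros((8, 4, 4)),
                                       n_permutations=100, seed=3)
        pos = [c for c in res.clusters if c.sign == 1]
        assert sorted(c.size for c in pos) == [1, 1]

    def test_invalid_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            cluster_size_permutation(np.zeros((4, 2, 2)), np.zeros((4, 2, 2)),
                                     alpha=1.5)


class TestPearson:
    def test_p_from_r_agrees_with_t_distribution(self):
        from phasealign import pearson_p_from_r
        t, p = pearson_p_from_r(0.6, 12)
        assert t == pytest.approx(0.6 * np.sqrt(10) / np.sqrt(1 - 0.36))
        assert p == pytest.approx(2 * sps.t.sf(t, df=10), rel=1e-12)

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12  # limiting case handled without division error

    def test_hand_computed_example(self):
        res = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_normal(9)
            y = rng.standard_normal(9)
            res = pearson_r(x, y)
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2)
                          * np.sum((y - y.mean()) ** 2))
            assert res.r == pytest.approx(num / den, abs=1e-12)
            r_sp, p_sp = sps.pearsonr(x, y)
            assert res.r == pytest.approx(r_sp, abs=1e-10)
            assert res.p == pytest.approx(p_sp, rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBHFDR:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_arithmetic_ladder_collapses(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, 0.04, atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_matches_step_up_definition(self, ps):
        ps = np.asarray(ps)
        adj, rej = bh_fdr(ps, q=0.05)
        m = ps.size
        order = np.argsort(ps)
        brute = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * ps[i] / rank)
            brute[i] = min(running, 1.0)
        np.testing.assert_allclose(adj, brute, atol=1e-12)
        np.testing.assert_array_equal(rej, brute <= 0.05)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(6)
        ps = rng.uniform(0.001, 1.0, 15)
        adj, _ = bh_fdr(ps)
        assert np.all(adj >= ps - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([1.2])


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        res = fisher_z_compare(0.5, 10, 0.5, 20)
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_example(self):
        res = fisher_z_compare(0.9, 7, 0.0, 7)
        assert res.z == pytest.approx(np.arctanh(0.9) / np.sqrt(0.5), abs=1e-4)
        assert res.z == pytest.approx(2.0821, abs=1e-3)
        assert res.p == pytest.approx(0.0374, abs=5e-4)

    def test_antisymmetry(self):
        a = fisher_z_compare(0.8, 12, 0.3, 9)
        b = fisher_z_compare(0.3, 9, 0.8, 12)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.5, 10)
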