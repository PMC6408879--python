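import dendropy
import numpy as np
import pytest

from aviamorph.phylo import phylo_covariance
from aviamorph.stats import (
    PhylogeneticMANOVA,
    compare_rates,
    manova_rrpp,
    pca,
    phylo_pls,
    sigma_mult,
)
from conftest import random_tree


def gls_anova_f_oracle(y, X, C):
    """Closed-form GLS ANOVA F by explicit matrix algebra (inv, not solve)."""
    Ci = np.linalg.inv(C)
    ones = np.ones((len(y), 1))

    def ss_res(design):
        b = np.linalg.inv(design.T @ Ci @ design) @ design.T @ Ci @ y
        r = y - design @ b
        return float(r.T @ Ci @ r)

    ss_full, ss_red = ss_res(X), ss_res(ones)
    df_m = X.shape[1] - 1
    df_r = len(y) - X.shape[1]
    return ((ss_red - ss_full) / df_m) / (ss_full / df_r)


class TestManova:
    def test_univariate_matches_closed_form_gls(self, rng):
        for _ in range(10):
            tree = random_tree(rng, 12)
            taxa = [l.taxon.label for l in tree.leaf_node_iter()]
            cov = phylo_covariance(tree, taxa)
            y = np.linalg.cholesky(cov.C) @ rng.normal(size=12)
            groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
            rng.shuffle(groups)
            res = manova_rrpp(y, groups, cov, iterations=99, seed=0)
            X = np.column_stack([np.ones(12), groups == "b", groups == "c"]).astype(float)
            assert res.F == pytest.approx(gls_anova_f_oracle(y, X, cov.C), abs=1e-10)

    def test_none_cov_equals_star_tree_cov(self, rng):
        n = 10
        Y = rng.normal(size=(n, 6))
        groups = ["a"] * 5 + ["b"] * 5
        star = dendropy.Tree.get(
            data="(" + ",".join(f"t{i}:1" for i in range(n)) + ");", schema="newick")
        cov = phylo_covariance(star, [f"t{i}" for i in range(n)])
        r1 = manova_rrpp(Y, groups, None, iterations=199, seed=5)
        r2 = manova_rrpp(Y, groups, cov, iterations=199, seed=5)
        assert (r1.F, r1.p, r1.Z) == (r2.F, r2.p, r2.Z)
        assert r1.SS_model == r2.SS_model

    def test_reproducible_and_p_positive(self, rng):
        Y = rng.normal(size=(12, 4))
        groups = ["a", "b", "c"] * 4
        r1 = manova_rrpp(Y, groups, None, iterations=199, seed=42)
        r2 = manova_rrpp(Y, groups, None, iterations=199, seed=42)
        assert r1.p == r2.p and r1.F == r2.F and r1.Z == r2.Z
        assert 0 < r1.p <= 1
        assert abs(r1.p * 200 - round(r1.p * 200)) < 1e-9  # resolution 1/(iters+1)

    def test_r2_bounds_and_partition(self, rng):
        Y = rng.normal(size=(15, 8))
        groups = ["a", "b", "c"] * 5
        res = manova_rrpp(Y, groups, None, iterations=99, seed=1)
        assert 0 <= res.R2 <= 1
        assert res.SS_model + res.SS_residual == pytest.approx(res.SS_total, rel=1e-12)

    def test_effect_size_monotone_in_group_separation(self, rng):
        """Z grows with the true group-mean displacement."""
        n, t = 45, 10
        base = rng.normal(size=(n, t))
        groups = np.array(["a", "b", "c"] * 15)
        zs = []
        for effect in (0.0, 1.0, 3.0):
            Y = base.copy()
            Y[groups == "b", 0] += effect
            Y[groups == "c", 1] += effect
            zs.append(manova_rrpp(Y, groups, None, iterations=499, seed=9).Z)
        assert zs[0] < zs[1] < zs[2]

    def test_single_group_error(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            PhylogeneticMANOVA(rng.normal(size=(6, 2)), ["a"] * 6)

    def test_degenerate_data_error(self):
        Y = np.ones((8, 3))
        with pytest.raises(ValueError, match="degenerate"):
            manova_rrpp(Y, ["a", "b"] * 4, None, iterations=99, seed=0)


class TestSigmaMult:
    def test_star_tree_hand_example(self):
        star = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        cov = phylo_covariance(star, ["A", "B", "C"])
        # y = (0,0,3): a = 1, d^2 = (1,1,4), sigma^2 = 6/3
        assert sigma_mult(np.array([0.0, 0.0, 3.0]), cov) == pytest.approx(2.0, abs=1e-12)

    def test_univariate_equals_quadratic_form(self, rng):
        for _ in range(25):
            tree = random_tree(rng, rng.integers(5, 20))
            taxa = [l.taxon.label for l in tree.leaf_node_iter()]
            cov = phylo_covariance(tree, taxa)
            y = rng.normal(size=len(taxa))
            Ci = np.linalg.inv(cov.C)
            ones = np.ones(len(taxa))
            a = (ones @ Ci @ y) / (ones @ Ci @ ones)
            r = y - a
            expected = float(r @ Ci @ r) / len(taxa)
            assert sigma_mult(y, cov) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_quadratic_scaling(self, rng):
        tree = random_tree(rng, 10)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        cov = phylo_covariance(tree, taxa)
        Y = rng.normal(size=(10, 7))
        assert sigma_mult(3.0 * Y, cov) == pytest.approx(9.0 * sigma_mult(Y, cov), rel=1e-12)

    def test_constant_traits_zero_rate(self, three_taxon_cov):
        assert sigma_mult(np.full((3, 4), 2.0), three_taxon_cov) == pytest.approx(0.0, abs=1e-12)


class TestCompareRates:
    def test_label_swap_symmetry(self, rng):
        tree = random_tree(rng, 16)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        cov = phylo_covariance(tree, taxa)
        Y = rng.normal(size=(16, 5))
        g1 = ["fast"] * 8 + ["slow"] * 8
        g2 = ["slow"] * 8 + ["fast"] * 8
        r1 = compare_rates(Y, g1, cov, nsim=99, seed=3)
        r2 = compare_rates(Y, g2, cov, nsim=99, seed=3)
        assert r1.observed_ratio == r2.observed_ratio
        assert r1.p == r2.p

    def test_p_invariant_to_common_simulation_rate(self, rng):
        tree = random_tree(rng, 12)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        cov = phylo_covariance(tree, taxa)
        Y = rng.normal(size=(12, 4))
        groups = ["a", "b"] * 6
        from aviamorph.stats import EvolutionaryRateComparison

        model = EvolutionaryRateComparison(Y, groups, cov)
        r1 = model.fit(nsim=99, seed=17, rate=1.0)
        r2 = model.fit(nsim=99, seed=17, rate=50.0)
        assert r1.p == r2.p
        assert r1.observed_ratio == r2.observed_ratio

    def test_reports_all_pairs(self, rng):
        tree = random_tree(rng, 12)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        cov = phylo_covariance(tree, taxa)
        res = compare_rates(rng.normal(size=(12, 3)), ["a", "b", "c"] * 4, cov, nsim=99, seed=0)
        assert set(res.pairwise_p) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert res.observed_ratio >= 1
        assert all(r >= 1 for r in res.pairwise_ratios.values())

    def test_singleton_group_error(self, rng):
        tree = random_tree(rng, 6)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        cov = phylo_covariance(tree, taxa)
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_rates(np.random.default_rng(0).normal(size=(6, 2)),
                          ["a"] * 5 + ["b"], cov, nsim=99, seed=0)

    def test_too_few_simulations_error(self, rng):
        tree = random_tree(rng, 6)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        cov = phylo_covariance(tree, taxa)
        with pytest.raises(ValueError, match="99"):
            compare_rates(rng.normal(size=(6, 2)), ["a", "b"] * 3, cov, nsim=50, seed=0)


class TestPls:
    def test_identical_blocks_perfect_correlation(self, rng):
        Y = rng.normal(size=(12, 5))
        res = phylo_pls(Y, Y.copy(), None, iterations=99, seed=0)
        assert res.r_pls[0] == pytest.approx(1.0, abs=1e-9)
        assert res.covariation_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rotation_of_block_preserves_r(self, rng):
        Y = rng.normal(size=(12, 5))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        res = phylo_pls(Y, Y @ Q, None, iterations=99, seed=0)
        assert res.r_pls[0] == pytest.approx(1.0, abs=1e-9)

    def test_reproducible(self, rng):
        Y1, Y2 = rng.normal(size=(10, 4)), rng.normal(size=(10, 6))
        r1 = phylo_pls(Y1, Y2, None, iterations=199, seed=21)
        r2 = phylo_pls(Y1, Y2, None, iterations=199, seed=21)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.r_pls, r2.r_pls)

    def test_phylogenetic_version_uses_whitening(self, rng):
        tree = random_tree(rng, 10)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        cov = phylo_covariance(tree, taxa)
        Y1, Y2 = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
        r_phylo = phylo_pls(Y1, Y2, cov, iterations=99, seed=0)
        r_plain = phylo_pls(Y1, Y2, None, iterations=99, seed=0)
        assert r_phylo.r_pls[0] != r_plain.r_pls[0]

    def test_too_few_taxa_error(self, rng):
        with pytest.raises(ValueError, match="3 taxa"):
            phylo_pls(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestPca:
    def test_collinear_points_single_axis(self):
        t = np.linspace(0, 1, 9)[:, None]
        Y = t @ np.array([[1.0, -2.0, 0.5]])
        res = pca(Y)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self, rng):
        res = pca(rng.normal(size=(10, 6)))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.variance_fraction >= 0)

    def test_scores_preserve_pairwise_distances(self, rng):
        Y = rng.normal(size=(8, 5))
        res = pca(Y)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(res.scores), pdist(Y - Y.mean(axis=0)), atol=1e-10)

    def test_axes_orthogonal(self, rng):
        res = pca(rng.normal(size=(12, 6)))
        G = res.components @ res.components.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-10)
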