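import networkx as nx
import numpy as np
import pytest
from scipy import stats

from admixkit.genotype_io import AlleleFreqTable
from admixkit.graphfit import (
    AdmixtureGraph,
    CovMatrix,
    add_migration_edges,
    composite_loglik,
    covariance_matrix,
    fit_tree,
    predicted_covariance,
    scaled_residuals,
    tree_fit_report,
    variance_explained,
)
from admixkit.simdata import (
    SimSpec,
    random_tree,
    sample_allele_freqs,
    simulate_frequencies,
    six_tip_migration_scenario,
)
from admixkit.tree_utils import rf_distance
from conftest import make_snps


def two_tip_tree(a=0.3, b=0.1):
    g = nx.DiGraph()
    g.add_edge("R", "A", kind="tree", length=a)
    g.add_edge("R", "B", kind="tree", length=b)
    return AdmixtureGraph(g, "R")


def noise_free_cov(graph, se=1e-3):
    pops = graph.tips()
    C = predicted_covariance(graph, pops)
    P = len(pops)
    return CovMatrix(pops, C, np.full((P, P), se), 2,
                     np.zeros((2, P, P)), np.array([1, 1]))


class TestPredictedCovariance:
    def test_two_tip_hand_centering(self):
        # uncentered V = diag(a, b); centered entries all (a+b)/4 in sign
        C = predicted_covariance(two_tip_tree(0.3, 0.1))
        expect = np.array([[0.1, -0.1], [-0.1, 0.1]])
        np.testing.assert_allclose(C, expect, atol=1e-12)

    def test_zero_branch_lengths_zero_matrix(self):
        C = predicted_covariance(two_tip_tree(0.0, 0.0))
        np.testing.assert_allclose(C, 0.0, atol=1e-15)

    def test_full_weight_migration_reproduces_source(self):
        rng = np.random.default_rng(0)
        tree = random_tree(list("ABCDE"), rng)
        g = tree.copy()
        edges = g.tree_edges()
        (src,) = [e for e in edges if e[1] == "A"]
        (dst,) = [e for e in edges if e[1] == "B"]
        g.add_migration(src, dst, 0.999)
        # oracle: at w -> 1 the recipient's shared drift with any third
        # population equals the source path's (checked uncentered, since
        # private drift below the attachment point differs)
        from admixkit.graphfit import path_coefficients

        U, branches, tips = path_coefficients(g)
        lengths = np.array([g.g.edges[e]["length"] for e in branches])
        V = (U * lengths) @ U.T
        a, b = tips.index("A"), tips.index("B")
        for x, name in enumerate(tips):
            if name in ("A", "B"):
                continue
            assert V[b, x] == pytest.approx(V[a, x], rel=0.01, abs=1e-12)

    def test_centered_psd_and_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            tree = random_tree([f"t{i}" for i in range(9)], rng)
            C = predicted_covariance(tree)
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() >= -1e-8
            np.testing.assert_allclose(C.sum(axis=1), 0, atol=1e-10)

    def test_invalid_weight_rejected(self):
        g = two_tip_tree()
        gg = g.copy()
        s = gg.insert_attachment(("R", "A"))
        d = gg.insert_attachment(("R", "B"))
        gg.g.add_edge(s, d, kind="migration", weight=1.5)
        with pytest.raises(ValueError):
            predicted_covariance(gg)


class TestCovarianceMatrix:
    def test_two_population_hand_arithmetic(self):
        # one usable SNP pair with freqs (0.2, 0.4): centered (-0.1, +0.1)
        counts = np.array([[2, 2], [4, 4], [3, 3]])
        totals = np.full((3, 2), 10)
        T = AlleleFreqTable(["A", "B", "C"], make_snps(2), counts, totals)
        cov = covariance_matrix(T, block=1)
        f = counts / totals
        Y = f - f.mean(axis=0)
        expect = (Y @ Y.T) / 2
        np.testing.assert_allclose(cov.W, expect, atol=1e-12)

    def test_identical_populations_zero_matrix(self):
        counts = np.tile(np.array([[3, 5, 2, 7]]), (4, 1))
        totals = np.full((4, 4), 10)
        T = AlleleFreqTable(list("ABCD"), make_snps(4), counts, totals)
        cov = covariance_matrix(T, block=2)
        np.testing.assert_allclose(cov.W, 0.0, atol=1e-12)

    def test_star_tree_closed_form(self):
        # equal drift c from the root: after centering the diagonal is
        # c(1 - 1/P) * het and off-diagonals -c/P * het
        rng = np.random.default_rng(2)
        P, c, n = 5, 0.04, 50_000
        p0 = rng.uniform(0.05, 0.95, size=n)
        het = p0 * (1 - p0)
        X = np.clip(p0 + rng.normal(0, np.sqrt(c * het), size=(P, n)), 0, 1)
        counts = np.round(X * 200).astype(int)
        T = AlleleFreqTable([f"P{i}" for i in range(P)], make_snps(n),
                            counts, np.full((P, n), 200))
        cov = covariance_matrix(T, block=20)
        scale = het.mean() * c
        diag = np.diag(cov.W).mean()
        off = cov.W[~np.eye(P, dtype=bool)].mean()
        assert diag == pytest.approx(scale * (1 - 1 / P), rel=0.10)
        assert off == pytest.approx(-scale / P, rel=0.10)

    def test_skips_zero_total_snps(self):
        counts = np.array([[2, 1], [3, 0], [1, 2]])
        totals = np.array([[10, 10], [10, 0], [10, 10]])
        T = AlleleFreqTable(list("ABC"), make_snps(2), counts, totals)
        with pytest.raises(ValueError, match="fewer than 2 usable"):
            covariance_matrix(T, block=1)

    def test_row_sums_vanish(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 21, size=(4, 100))
        T = AlleleFreqTable(list("ABCD"), make_snps(100), counts,
                            np.full((4, 100), 20))
        cov = covariance_matrix(T, block=20)
        np.testing.assert_allclose(cov.W.sum(axis=1), 0, atol=1e-10)


class TestCompositeLoglik:
    def test_perfect_fit_is_maximum(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(4, 4))
        W = (W + W.T) / 2
        SE = np.full((4, 4), 0.2)
        iu = np.triu_indices(4)
        lmax = composite_loglik(W, SE, W)
        assert lmax == pytest.approx(
            np.sum(stats.norm.logpdf(0, scale=SE[iu])))
        assert composite_loglik(W, SE, W + 0.1) < lmax

    def test_doubling_residuals_lowers_loglik(self):
        rng = np.random.default_rng(5)
        W = rng.normal(size=(3, 3))
        W = (W + W.T) / 2
        C = W + 0.05
        SE = np.full((3, 3), 0.1)
        assert composite_loglik(W, SE, W + 0.1) < composite_loglik(W, SE, C)

    def test_matches_direct_summation(self):
        W = np.array([[0.02, -0.01, -0.01],
                      [-0.01, 0.03, -0.02],
                      [-0.01, -0.02, 0.03]])
        C = W * 0.9
        SE = np.full((3, 3), 0.005)
        expect = 0.0
        for i in range(3):
            for j in range(i, 3):
                expect += stats.norm.logpdf(W[i, j], C[i, j], SE[i, j])
        assert composite_loglik(W, SE, C) == pytest.approx(expect)

    def test_nonpositive_se_rejected(self):
        W = np.zeros((3, 3))
        with pytest.raises(ValueError):
            composite_loglik(W, np.zeros((3, 3)), W)


class TestFitTree:
    def test_recovers_known_topologies_noise_free(self):
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(20):
            tree = random_tree([f"t{i}" for i in range(8)], rng)
            cov = noise_free_cov(tree)
            best = fit_tree(cov, "t0", n_searches=1, seed=rep)[0][0]
            hits += rf_distance(best, tree) == 0
            ve = variance_explained(
                cov.W, predicted_covariance(best, cov.populations))
            assert ve >= 0.999
        assert hits >= 19

    def test_four_tip_branch_lengths_recovered(self):
        rng = np.random.default_rng(7)
        tree = random_tree(list("ABCD"), rng, branch_scale=0.05)
        cov = noise_free_cov(tree, se=1e-5)
        best = fit_tree(cov, "A", n_searches=1, seed=0)[0][0]
        C = predicted_covariance(best, cov.populations)
        np.testing.assert_allclose(C, cov.W, atol=1e-6)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        tree = random_tree([f"t{i}" for i in range(6)], rng)
        cov = noise_free_cov(tree)
        ll1 = fit_tree(cov, "t0", n_searches=1, seed=0)[0][1]
        perm = rng.permutation(6)
        pops2 = [cov.populations[i] for i in perm]
        cov2 = CovMatrix(pops2, cov.W[np.ix_(perm, perm)],
                         cov.SE[np.ix_(perm, perm)], cov.n_blocks,
                         cov.block_sums, cov.block_nsnps)
        ll2 = fit_tree(cov2, "t0", n_searches=1, seed=0)[0][1]
        assert ll1 == pytest.approx(ll2, rel=1e-6)

    def test_too_few_populations_rejected(self):
        cov = noise_free_cov(two_tip_tree())
        with pytest.raises(ValueError):
            fit_tree(cov, "A")

    def test_unknown_outgroup_rejected(self):
        rng = np.random.default_rng(9)
        cov = noise_free_cov(random_tree(list("ABCD"), rng))
        with pytest.raises(ValueError, match="outgroup"):
            fit_tree(cov, "Z")


@pytest.fixture(scope="module")
def fitted_scenario():
    graph, true_edge, w = six_tip_migration_scenario(w=0.4)
    spec = SimSpec(graph=graph, n_snps=5000, samples_per_pop=20, seed=5)
    freqs, snp_map, _ = simulate_frequencies(spec)
    table = sample_allele_freqs(freqs, spec, snp_map)
    cov = covariance_matrix(table, block=20)
    tree = fit_tree(cov, "out", n_searches=1, seed=0)[0][0]
    return graph, true_edge, cov, tree


class TestMigrationEdges:

    def test_zero_edges_is_tree_fit(self, fitted_scenario):
        _, _, cov, tree = fitted_scenario
        rep = add_migration_edges(tree, cov, 0, seed=0)
        base = tree_fit_report(tree, cov)
        assert rep.migrations == []
        assert rep.loglik == pytest.approx(base.loglik)

    def test_edge_improves_loglik_and_variance(self, fitted_scenario):
        _, _, cov, tree = fitted_scenario
        base = tree_fit_report(tree, cov)
        rep = add_migration_edges(tree, cov, 1, seed=0,
                                  compute_pvalues=False)
        assert rep.loglik >= base.loglik
        assert rep.variance_explained > base.variance_explained

    def test_recovered_edge_and_weight(self, fitted_scenario):
        from admixkit.edge_support import edge_match

        _, true_edge, cov, tree = fitted_scenario
        rep = add_migration_edges(tree, cov, 1, seed=0)
        (info,) = rep.migrations
        assert edge_match((info.origin_tips, info.dest_tips), true_edge,
                          "extended")
        assert 0.3 <= info.weight <= 0.5
        assert info.se is not None and info.p is not None
        assert info.p < 0.05  # a strong true edge should be significant


class TestVarianceExplained:
    def test_perfect_fit_is_one(self):
        W = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert variance_explained(W, W) == pytest.approx(1.0)

    def test_mean_model_is_zero(self):
        rng = np.random.default_rng(10)
        W = rng.normal(size=(4, 4))
        W = (W + W.T) / 2
        iu = np.triu_indices(4)
        mean = np.full_like(W, W[iu].mean())
        assert variance_explained(W, mean) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computation(self):
        W = np.array([[2.0, 0.0, 1.0], [0.0, 2.0, 0.0], [1.0, 0.0, 3.0]])
        C = W - 0.5
        iu = np.triu_indices(3)
        w = W[iu]
        expect = 1 - (0.25 * len(w)) / ((w - w.mean()) ** 2).sum()
        assert variance_explained(W, C) == pytest.approx(expect)

    def test_constant_matrix_rejected(self):
        W = np.ones((3, 3))
        with pytest.raises(ValueError):
            variance_explained(W, W * 0.5)


class TestScaledResiduals:
    def test_perfect_fit_zero(self):
        W = np.eye(3)
        out = scaled_residuals(W, W, np.full((3, 3), 0.1))
        np.testing.assert_allclose(out, 0.0)

    def test_elementwise_arithmetic(self):
        W = np.array([[0.4, 0.1], [0.1, 0.2]])
        C = np.array([[0.3, 0.2], [0.2, 0.1]])
        SE = np.array([[0.05, 0.1], [0.1, 0.05]])
        out = scaled_residuals(W, C, SE)
        np.testing.assert_allclose(out, (W - C) / SE)
        np.testing.assert_allclose(out, out.T)
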