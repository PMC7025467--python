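import numpy as np
import pytest

from admixkit.fstats import (
    block_jackknife,
    f3_admixture,
    f3_outgroup,
    f4,
    holm_bonferroni,
    zdiff_outgroup,
)
from admixkit.genotype_io import AlleleFreqTable
from admixkit.simdata import (
    SimSpec,
    admixture_f3_scenario,
    balanced_tree,
    sample_allele_freqs,
    simulate_frequencies,
)
from conftest import make_snps


def table_from_freqs(freq_rows, pops, totals=1000):
    """Exact-frequency table (huge totals so sampling noise vanishes)."""
    f = np.asarray(freq_rows, dtype=float)
    counts = np.round(f * totals).astype(int)
    t = np.full(f.shape, totals, dtype=int)
    return AlleleFreqTable(pops, make_snps(f.shape[1]), counts, t)


def simulated_table(graph, n_snps=4000, seed=0, samples=20):
    spec = SimSpec(graph=graph, n_snps=n_snps, samples_per_pop=samples,
                   seed=seed)
    freqs, snp_map, _ = simulate_frequencies(spec)
    return sample_allele_freqs(freqs, spec, snp_map)


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        est, se, _ = block_jackknife([2.0] * 5, [1] * 5)
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_equal_blocks_match_textbook_delete1(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 4))  # 10 blocks of 4 SNPs
        sums = vals.sum(axis=1)
        est, se, loo = block_jackknife(sums, [4] * 10)
        # enumeration oracle: classic delete-1 jackknife on equal blocks
        n = 40
        theta = sums.sum() / n
        loo_o = np.array([(sums.sum() - s) / (n - 4) for s in sums])
        se_o = np.sqrt((10 - 1) / 10 * ((loo_o - loo_o.mean()) ** 2).sum())
        assert est == pytest.approx(theta)
        assert se == pytest.approx(se_o, rel=1e-10)
        np.testing.assert_allclose(loo, loo_o)

    def test_se_close_to_analytic_for_iid_data(self):
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(50):
            x = rng.normal(0, 1, size=1000)
            sums = x.reshape(50, 20).sum(axis=1)
            _, se, _ = block_jackknife(sums, [20] * 50)
            ratios.append(se / (1 / np.sqrt(1000)))
        assert 0.8 < np.mean(ratios) < 1.25

    def test_single_block_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            block_jackknife([1.0], [10])


class TestF3Admixture:
    def test_midpoint_admixture_value(self):
        # x = 0.5, y = 0, w = 1 at every SNP: (x-y)(x-w) = -0.25
        T = table_from_freqs([[0.5] * 40, [0.0] * 40, [1.0] * 40],
                             ["X", "Y", "W"])
        r = f3_admixture(T, "X", "Y", "W", block=10, bias_correct=False)
        assert r.estimate == pytest.approx(-0.25)

    def test_identical_references_nonnegative(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 0.9, 40)
        y = rng.uniform(0.1, 0.9, 40)
        T = table_from_freqs([x, y, y], ["X", "Y", "W"])
        xq, yq = (T.counts / T.totals)[0], (T.counts / T.totals)[1]
        r = f3_admixture(T, "X", "Y", "W", block=10, bias_correct=False)
        assert r.estimate >= 0
        assert r.estimate == pytest.approx(np.mean((xq - yq) ** 2))

    def test_matches_per_snp_enumeration(self, hand_freq_table):
        T = hand_freq_table
        r = f3_admixture(T, "P1", "P2", "P3", block=3, bias_correct=True)
        f = T.counts / T.totals
        u = [(f[0, s] - f[1, s]) * (f[0, s] - f[2, s])
             - f[0, s] * (1 - f[0, s]) / (T.totals[0, s] - 1)
             for s in range(6)]
        assert r.estimate == pytest.approx(np.mean(u))

    def test_symmetric_in_references(self, hand_freq_table):
        a = f3_admixture(hand_freq_table, "P1", "P2", "P3", block=3)
        b = f3_admixture(hand_freq_table, "P1", "P3", "P2", block=3)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.z == pytest.approx(b.z)

    def test_duplicate_population_rejected(self, hand_freq_table):
        with pytest.raises(ValueError, match="distinct"):
            f3_admixture(hand_freq_table, "P1", "P1", "P2")

    def test_admixed_population_detected(self):
        zs = [f3_admixture(simulated_table(admixture_f3_scenario(),
                                           seed=s), "X", "Y", "W").z
              for s in range(5)]
        assert all(z < -3 for z in zs)


class TestF4:
    def test_identical_last_args_zero(self, hand_freq_table):
        T = hand_freq_table
        f = T.counts / T.totals
        T2 = table_from_freqs([f[0], f[1], f[2], f[2]],
                              ["X", "Y", "W", "Z"])
        r = f4(T2, "X", "Y", "W", "Z", block=3)
        assert r.estimate == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self, hand_freq_table):
        a = f4(hand_freq_table, "P1", "P2", "P3", "P4", block=3)
        b = f4(hand_freq_table, "P2", "P1", "P3", "P4", block=3)
        assert a.estimate == pytest.approx(-b.estimate)
        assert abs(a.z) == pytest.approx(abs(b.z))

    def test_pair_swap_symmetry(self, hand_freq_table):
        a = f4(hand_freq_table, "P1", "P2", "P3", "P4", block=3)
        b = f4(hand_freq_table, "P3", "P4", "P1", "P2", block=3)
        assert a.estimate == pytest.approx(b.estimate)

    def test_additivity_across_middle_population(self):
        tree = balanced_tree(8, 0.02)
        T = simulated_table(tree, seed=7)
        whole = f4(T, "t0", "t1", "t2", "t4").estimate
        part1 = f4(T, "t0", "t1", "t2", "t6").estimate
        part2 = f4(T, "t0", "t1", "t6", "t4").estimate
        se = f4(T, "t0", "t1", "t2", "t4").se
        assert whole == pytest.approx(part1 + part2, abs=4 * se + 1e-9)

    def test_null_calibration_on_tree(self):
        zs = [f4(simulated_table(balanced_tree(8, 0.02), seed=s),
                 "t0", "t1", "t4", "t5").z for s in range(10)]
        assert -1 < np.mean(zs) < 1
        assert sum(abs(z) > 3 for z in zs) <= 1


class TestOutgroupF3:
    def test_self_comparison_upper_bound(self):
        rng = np.random.default_rng(3)
        o = rng.uniform(0.2, 0.8, 40)
        t = rng.uniform(0.2, 0.8, 40)
        T = table_from_freqs([o, t, t], ["O", "T", "R"])
        oq, tq = (T.counts / T.totals)[0], (T.counts / T.totals)[1]
        r = f3_outgroup(T, "O", "T", "R", block=10)
        assert r.estimate == pytest.approx(np.mean((oq - tq) ** 2))
        assert r.estimate >= 0

    def test_sister_scores_higher_than_distant(self):
        # t2 sister to t3; t4 distant; outgroup from the other half
        wins = 0
        for s in range(10):
            T = simulated_table(balanced_tree(8, 0.02), seed=100 + s)
            near = f3_outgroup(T, "t7", "t2", "t3").estimate
            far = f3_outgroup(T, "t7", "t2", "t4").estimate
            wins += near > far
        assert wins >= 9

    def test_driftless_tree_gives_zero(self):
        # without drift the only signal is apex sampling noise, which the
        # bias correction removes exactly
        tree = balanced_tree(4, 0.0)
        T = simulated_table(tree, seed=11, samples=50)
        r = f3_outgroup(T, "t0", "t1", "t2", bias_correct=True)
        assert abs(r.z) < 3


class TestZDiff:
    def test_identical_references_zero(self, hand_freq_table):
        # r1 == r2 in counts: paired difference is identically zero
        T = hand_freq_table
        f = T.counts / T.totals
        T2 = table_from_freqs([f[0], f[1], f[2], f[2]],
                              ["O", "T", "R1", "R2"])
        z = zdiff_outgroup(T2, "O", "T", "R1", "R2", block=3)
        assert z.zdiff == pytest.approx(0.0, abs=1e-9)

    def test_clear_sister_vs_distant_is_decisive(self):
        wins = 0
        for s in range(10):
            T = simulated_table(balanced_tree(8, 0.02), seed=200 + s)
            z = zdiff_outgroup(T, "t7", "t2", "t3", "t4")
            wins += z.zdiff > 3
        assert wins >= 9


class TestHolmBonferroni:
    def test_single_test_is_plain_alpha(self):
        reject, adj = holm_bonferroni([0.03], alpha=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.03)
        reject, _ = holm_bonferroni([0.08], alpha=0.05)
        assert not reject[0]

    def test_step_down_rule_hand_enumeration(self):
        # m=3: 0.01 <= 0.05/3 reject; 0.03 > 0.05/2 stop
        reject, adj = holm_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
        assert list(reject) == [True, False, False]
        assert adj[0] == pytest.approx(0.03)
        assert adj[1] == pytest.approx(0.06)

    def test_all_ones_boundary(self):
        reject, adj = holm_bonferroni([1.0, 1.0])
        assert not reject.any()
        assert (adj == 1.0).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 0.2, 8)
        perm = rng.permutation(8)
        r1, a1 = holm_bonferroni(p)
        r2, a2 = holm_bonferroni(p[perm])
        np.testing.assert_array_equal(r1[perm], r2)
        np.testing.assert_allclose(a1[perm], a2)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])
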