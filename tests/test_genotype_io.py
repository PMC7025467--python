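import gzip

import numpy as np
import pandas as pd
import pytest

from admixkit.genotype_io import (
    MISSING,
    UNANCHORED,
    AlleleFreqTable,
    FormatError,
    GenotypeMatrix,
    minor_allele_recode,
    read_genotype_table,
    read_treemix_freqs,
    stratified_allele_freqs,
    write_genotype_table,
    write_treemix_freqs,
)
from conftest import make_snps


def write_tsv_fixture(tmp_path, rows, snp_map_lines):
    path = tmp_path / "geno.tsv"
    path.write_text("\n".join(rows) + "\n")
    (tmp_path / "geno.tsv.map").write_text("\n".join(snp_map_lines) + "\n")
    return path


class TestReadGenotypeTable:
    def test_tsv_round_trip_identity(self, tmp_path, small_genotypes):
        write_genotype_table(small_genotypes, tmp_path / "g.tsv")
        back = read_genotype_table(tmp_path / "g.tsv", "tsv")
        assert back.samples == small_genotypes.samples
        np.testing.assert_array_equal(back.calls, small_genotypes.calls)
        assert list(back.snps["id"]) == list(small_genotypes.snps["id"])

    def test_invalid_call_names_line(self, tmp_path):
        path = write_tsv_fixture(
            tmp_path,
            ["sample\tsnp0\tsnp1", "s1\t0\t3", "s2\t1\t2"],
            ["snp0\t1\t100", "snp1\t1\t200"],
        )
        with pytest.raises(FormatError, match="line 2"):
            read_genotype_table(path, "tsv")

    def test_out_of_order_snps_sorted_by_position(self, tmp_path):
        path = write_tsv_fixture(
            tmp_path,
            ["sample\ta\tb\tc", "s1\t0\t1\t2", "s2\t2\t1\t0"],
            ["a\t2\t100", "b\t1\t500", "c\t1\t100"],
        )
        G = read_genotype_table(path, "tsv")
        # sort oracle: (chrom, pos) ascending
        expect = sorted([("a", 2, 100), ("b", 1, 500), ("c", 1, 100)],
                        key=lambda t: (t[1], t[2]))
        assert list(G.snps["id"]) == [e[0] for e in expect]
        # calls must travel with their SNPs
        np.testing.assert_array_equal(G.calls[:, list(G.snps["id"]).index("a")],
                                      [0, 2])

    def test_unanchored_snps_retained_and_sorted_last(self, tmp_path):
        path = write_tsv_fixture(
            tmp_path,
            ["sample\ta\tb", "s1\t0\t1"],
            ["a\tscaffold_7\t100", "b\t3\t100"],
        )
        G = read_genotype_table(path, "tsv")
        assert list(G.snps["id"]) == ["b", "a"]
        assert G.snps["chrom"].iloc[1] == UNANCHORED

    def test_duplicate_snp_id_rejected(self, tmp_path):
        (tmp_path / "d.map").write_text("1 rs1 0 100\n2 rs1 0 200\n")
        (tmp_path / "d.ped").write_text("f1 s1 0 0 0 -9 A A G G\n")
        with pytest.raises(FormatError, match="duplicate SNP id"):
            read_genotype_table(tmp_path / "d", "plink-text")

    def test_plink_text_pair(self, tmp_path):
        (tmp_path / "d.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "d.ped").write_text(
            "f1 s1 0 0 0 -9 A A G T\n"
            "f1 s2 0 0 0 -9 A C T T\n"
        )
        G = read_genotype_table(tmp_path / "d", "plink-text")
        assert G.samples == ["s1", "s2"]
        # counted allele = first seen (A at rs1, G at rs2)
        np.testing.assert_array_equal(G.calls, [[2, 1], [1, 0]])

    def test_plink_missing_genotype(self, tmp_path):
        (tmp_path / "d.map").write_text("1 rs1 0 100\n")
        (tmp_path / "d.ped").write_text(
            "f1 s1 0 0 0 -9 0 0\nf1 s2 0 0 0 -9 A A\n")
        G = read_genotype_table(tmp_path / "d", "plink-text")
        assert G.calls[0, 0] == MISSING


class TestStratifiedAlleleFreqs:
    def test_direct_count(self):
        calls = np.array([[0], [2]], dtype=np.int8)
        G = GenotypeMatrix(["a", "b"], make_snps(1), calls)
        T = stratified_allele_freqs(G, {"a": "P", "b": "P"})
        assert T.counts[0, 0] == 2 and T.totals[0, 0] == 4

    def test_missing_call_excluded(self):
        calls = np.array([[1], [MISSING]], dtype=np.int8)
        G = GenotypeMatrix(["a", "b"], make_snps(1), calls)
        T = stratified_allele_freqs(G, {"a": "P", "b": "P"})
        assert (T.counts[0, 0], T.totals[0, 0]) == (1, 2)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        n_s, n_snp = 9, 12
        calls = rng.integers(0, 3, size=(n_s, n_snp)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.2] = MISSING
        samples = [f"s{i}" for i in range(n_s)]
        pops = {s: f"P{i % 3}" for i, s in enumerate(samples)}
        G = GenotypeMatrix(samples, make_snps(n_snp), calls)
        T = stratified_allele_freqs(G, pops)
        for pi, p in enumerate(T.populations):
            for j in range(n_snp):
                c = t = 0
                for i, s in enumerate(samples):
                    if pops[s] == p and calls[i, j] != MISSING:
                        c += calls[i, j]
                        t += 2
                assert (T.counts[pi, j], T.totals[pi, j]) == (c, t)

    def test_allele_conservation(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(6, 8)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = MISSING
        samples = [f"s{i}" for i in range(6)]
        G = GenotypeMatrix(samples, make_snps(8), calls)
        T = stratified_allele_freqs(G, {s: f"P{i % 2}" for i, s in
                                        enumerate(samples)})
        obs = np.where(calls == MISSING, 0, calls).sum(axis=0)
        np.testing.assert_array_equal(T.counts.sum(axis=0), obs)

    def test_unlabeled_sample_rejected(self, small_genotypes):
        with pytest.raises(ValueError, match="no population label"):
            stratified_allele_freqs(small_genotypes, {"s1": "P"})


class TestMinorAlleleRecode:
    def test_major_counted_allele_flipped(self):
        calls = np.array([[2, 0], [2, 1], [1, 2]], dtype=np.int8)
        G = GenotypeMatrix(["a", "b", "c"], make_snps(2), calls)
        R = minor_allele_recode(G)
        freq = R.calls.astype(float).mean(axis=0) / 2
        assert (freq <= 0.5).all()
        # flipping twice is the identity
        np.testing.assert_array_equal(minor_allele_recode(R).calls, R.calls)


class TestTreemixFormat:
    def test_format_definition(self, tmp_path):
        T = AlleleFreqTable(["P1", "P2"], make_snps(1),
                            np.array([[2], [0]]), np.array([[4], [6]]))
        path = tmp_path / "f.gz"
        write_treemix_freqs(T, path)
        with gzip.open(path, "rt") as fh:
            lines = [ln.strip() for ln in fh if not ln.startswith("#")]
        assert lines == ["P1 P2", "2,2 0,6"]

    def test_round_trip_on_simulated_table(self, tmp_path):
        rng = np.random.default_rng(2)
        n_pop, n_snp = 30, 1000
        totals = 2 * rng.integers(2, 41, size=(n_pop, 1)) * np.ones(
            (1, n_snp), dtype=int)
        counts = rng.binomial(totals, rng.uniform(0.05, 0.95, size=n_snp))
        T = AlleleFreqTable([f"P{i}" for i in range(n_pop)],
                            make_snps(n_snp), counts, totals)
        path = tmp_path / "f.gz"
        write_treemix_freqs(T, path)
        back = read_treemix_freqs(path, snps=T.snps)
        assert back.populations == T.populations
        np.testing.assert_array_equal(back.counts, T.counts)
        np.testing.assert_array_equal(back.totals, T.totals)

    def test_column_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("P1 P2\n2,2\n")
        with pytest.raises(FormatError, match="columns"):
            read_treemix_freqs(path)

    def test_negative_pair_rejected(self, tmp_path):
        path = tmp_path / "bad.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("P1\n-1,3\n")
        with pytest.raises(FormatError):
            read_treemix_freqs(path)


class TestInvariants:
    def test_call_domain_enforced(self):
        with pytest.raises(ValueError, match="invalid call"):
            GenotypeMatrix(["s"], make_snps(1),
                           np.array([[3]], dtype=np.int8))

    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            AlleleFreqTable(["P"], make_snps(1),
                            np.array([[5]]), np.array([[4]]))
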