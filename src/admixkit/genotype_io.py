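"""Genotype and allele-frequency I/O.

Data units
----------
A :class:`GenotypeMatrix` holds diploid biallelic calls (0/1/2 copies of the
counted allele, -1 = missing) for samples x SNPs, with a per-SNP map of
chromosome and physical position.  A :class:`AlleleFreqTable` holds, per
population and SNP, the count of the counted allele and the total number of
sampled alleles (2 x non-missing diploid individuals) -- the exchange unit of
the TreeMix frequency format.

Formats
-------
* ``tsv`` -- a genotype table with a header row of SNP ids, one row per sample
  (first column the sample id), plus a sidecar ``<path>.map`` file with
  whitespace-separated columns ``id chrom pos`` (and optionally two allele
  columns).  Chromosomes outside the integer range carry the label
  ``"unanchored"``.
* ``plink-text`` -- .ped/.map pair: the .map has columns
  ``chrom id cM(ignored) bp``; the .ped has family/sample id, four ignored
  columns, then two allele characters per SNP (``0`` = missing).
* TreeMix frequencies -- gzip text, line 1 the population labels, then one
  line per SNP of ``a,b`` pairs (counted allele count, other allele count).

The counted allele is, by convention, the minor allele computed on the full
dataset before any stratification; this is recorded in a header comment of
the TreeMix output.  f-statistics and the drift covariance are invariant to
consistent allele flips, so the convention only needs to be applied
consistently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
UNANCHORED = "unanchored"

__all__ = [
    "MISSING",
    "UNANCHORED",
    "GenotypeMatrix",
    "AlleleFreqTable",
    "read_genotype_table",
    "write_genotype_table",
    "stratified_allele_freqs",
    "minor_allele_recode",
    "write_treemix_freqs",
    "read_treemix_freqs",
]


class FormatError(ValueError):
    """A malformed genotype, map or frequency file."""


def _normalize_chrom(raw) -> object:
    """Map a raw chromosome label to an int, or the 'unanchored' sentinel."""
    s = str(raw).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        return int(s)
    except ValueError:
        return UNANCHORED


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid calls with per-SNP genome coordinates.

    Attributes
    ----------
    samples : list of sample ids.
    snps : DataFrame with columns ``id``, ``chrom`` (int or "unanchored"),
        ``pos`` (bp), ``a1``, ``a2`` (counted allele first), in genome order.
    calls : int8 array (n_samples, n_snps), values in {0, 1, 2, -1}.
    """

    samples: list
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.samples[i]!r}, SNP {self.snps['id'].iloc[j]!r}"
            )
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def anchored_mask(self, chrom_range=range(1, 20)) -> np.ndarray:
        return self.snps["chrom"].isin(list(chrom_range)).to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index], self.snps.copy(), self.calls[index]
        )

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            list(self.samples), self.snps.iloc[index].copy(), self.calls[:, index]
        )

    def sort_genome_order(self) -> "GenotypeMatrix":
        """Stable sort of SNPs by (chromosome, position); unanchored SNPs last."""
        chrom_key = [
            (0, c) if c != UNANCHORED else (1, 10**9) for c in self.snps["chrom"]
        ]
        order = pd.DataFrame(
            {"k": chrom_key, "pos": self.snps["pos"].to_numpy()}
        ).sort_values(["k", "pos"], kind="stable").index.to_numpy()
        return self.take_snps(order)


@dataclass
class AlleleFreqTable:
    """Per-population biallelic allele counts per SNP.

    ``counts[p, s]`` is the number of counted-allele copies observed in
    population ``p`` at SNP ``s``; ``totals[p, s]`` the number of sampled
    alleles there (2 x non-missing individuals, hence even).
    """

    populations: list
    snps: pd.DataFrame
    counts: np.ndarray
    totals: np.ndarray
    counted_allele_note: str = field(default="", compare=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        shape = (len(self.populations), len(self.snps))
        if self.counts.shape != shape or self.totals.shape != shape:
            raise ValueError("counts/totals shape inconsistent with labels")
        if (self.counts < 0).any() or (self.counts > self.totals).any():
            raise ValueError("allele counts must satisfy 0 <= count <= total")
        if (self.totals % 2 != 0).any():
            raise ValueError("totals must be even (diploid samples)")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def freqs(self) -> np.ndarray:
        """Sample allele frequencies; NaN where a population has no data."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.counts / self.totals, np.nan)

    def take_snps(self, index) -> "AlleleFreqTable":
        index = np.asarray(index)
        return AlleleFreqTable(
            list(self.populations),
            self.snps.iloc[index].copy(),
            self.counts[:, index],
            self.totals[:, index],
            self.counted_allele_note,
        )

    def select_populations(self, names) -> "AlleleFreqTable":
        idx = [self.populations.index(n) for n in names]
        return AlleleFreqTable(
            list(names), self.snps.copy(), self.counts[idx], self.totals[idx],
            self.counted_allele_note,
        )


# ---------------------------------------------------------------------------
# genotype tables


def _read_map(path) -> pd.DataFrame:
    """Sidecar map for the TSV dialect: columns id chrom pos [a1 a2]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected 'id chrom pos', got {line!r}")
            row = {
                "id": parts[0],
                "chrom": _normalize_chrom(parts[1]),
                "pos": int(parts[2]),
            }
            if len(parts) >= 5:
                row["a1"], row["a2"] = parts[3], parts[4]
            rows.append(row)
    df = pd.DataFrame(rows)
    if "a1" not in df:
        df["a1"], df["a2"] = "A", "B"
    return df


def _read_tsv(path) -> GenotypeMatrix:
    geno = pd.read_csv(path, sep="\t", dtype=str)
    snp_ids = list(geno.columns[1:])
    snp_map = _read_map(str(path) + ".map").set_index("id")
    missing_ids = [s for s in snp_ids if s not in snp_map.index]
    if missing_ids:
        raise FormatError(f"SNP {missing_ids[0]!r} absent from map file")
    samples = geno.iloc[:, 0].tolist()
    calls = np.full((len(samples), len(snp_ids)), MISSING, dtype=np.int8)
    for j, snp in enumerate(snp_ids):
        col = geno[snp]
        for i, v in enumerate(col):
            v = "" if pd.isna(v) else str(v).strip()
            if v in ("", "NA", ".", "-1"):
                continue
            if v not in ("0", "1", "2"):
                # +2: header row and 1-based numbering of the data line
                raise FormatError(
                    f"{path}: line {i + 2}: invalid call {v!r} for SNP {snp}"
                )
            calls[i, j] = int(v)
    snps = snp_map.loc[snp_ids].reset_index()[["id", "chrom", "pos", "a1", "a2"]]
    return GenotypeMatrix(samples, snps, calls)


def _read_plink_text(path) -> GenotypeMatrix:
    """.ped/.map pair; `path` may be the prefix or either file."""
    prefix = str(path)
    for suf in (".ped", ".map"):
        if prefix.endswith(suf):
            prefix = prefix[: -len(suf)]
    map_rows = []
    with open(prefix + ".map") as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{prefix}.map:{ln}: expected 4 columns")
            map_rows.append(
                {"id": parts[1], "chrom": _normalize_chrom(parts[0]),
                 "pos": int(parts[3])}
            )
    snps = pd.DataFrame(map_rows)
    n_snps = len(snps)
    samples, genos = [], []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{prefix}.ped:{ln}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            genos.append(parts[6:])
    # determine the two alleles per SNP, counted allele = first seen
    a1 = [None] * n_snps
    a2 = [None] * n_snps
    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for i, g in enumerate(genos):
        for j in range(n_snps):
            x, y = g[2 * j], g[2 * j + 1]
            if x == "0" or y == "0":
                continue
            c = 0
            for al in (x, y):
                if a1[j] is None:
                    a1[j] = al
                if al == a1[j]:
                    c += 1
                elif a2[j] is None:
                    a2[j] = al
                elif al != a2[j]:
                    raise FormatError(
                        f"{prefix}.ped: SNP {snps['id'][j]} has >2 alleles"
                    )
            calls[i, j] = c
    snps["a1"] = [a if a is not None else "A" for a in a1]
    snps["a2"] = [a if a is not None else "B" for a in a2]
    return GenotypeMatrix(samples, snps, calls)


def read_genotype_table(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix and return it with SNPs in genome order.

    Parameters
    ----------
    path : file path (TSV) or PLINK prefix / .ped / .map path.
    format : "tsv" or "plink-text".

    SNPs without an integer chromosome assignment are retained with the
    chromosome label ``"unanchored"`` and sorted after anchored SNPs.
    """
    if format == "tsv":
        G = _read_tsv(path)
    elif format == "plink-text":
        G = _read_plink_text(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    dup = G.snps["id"].duplicated()
    if dup.any():
        raise FormatError(f"duplicate SNP id {G.snps['id'][dup].iloc[0]!r}")
    if pd.Index(G.samples).duplicated().any():
        raise FormatError("duplicate sample id")
    return G.sort_genome_order()


def write_genotype_table(G: GenotypeMatrix, path) -> None:
    """Write the TSV dialect (genotype table + sidecar .map)."""
    df = pd.DataFrame(
        {sid: G.calls[:, j] for j, sid in enumerate(G.snps["id"])},
        index=pd.Index(G.samples, name="sample"),
    ).astype(object)
    df = df.where(df != MISSING, "NA")
    df.to_csv(path, sep="\t")
    with open(str(path) + ".map", "w") as fh:
        for _, r in G.snps.iterrows():
            fh.write(f"{r['id']}\t{r['chrom']}\t{r['pos']}\t{r.get('a1', 'A')}"
                     f"\t{r.get('a2', 'B')}\n")


# ---------------------------------------------------------------------------
# stratified allele frequencies


def minor_allele_recode(G: GenotypeMatrix) -> GenotypeMatrix:
    """Recode calls so the counted allele is the dataset-wide minor allele.

    SNPs whose counted-allele frequency exceeds 0.5 get calls flipped
    (0 <-> 2) and the allele pair swapped.  Ties (freq exactly 0.5) keep the
    current orientation.
    """
    miss = G.missing_mask()
    calls = np.ma.masked_array(G.calls, miss)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = calls.sum(axis=0).filled(0) / np.maximum(2 * n_obs, 1)
    flip = freq > 0.5
    new_calls = G.calls.copy()
    new_calls[:, flip] = np.where(
        new_calls[:, flip] == MISSING, MISSING, 2 - new_calls[:, flip]
    )
    snps = G.snps.copy()
    if flip.any() and "a1" in snps:
        a1 = snps["a1"].to_numpy().copy()
        a2 = snps["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip], a1[flip].copy()
        snps["a1"], snps["a2"] = a1, a2
    return GenotypeMatrix(list(G.samples), snps, new_calls)


def stratified_allele_freqs(G: GenotypeMatrix, pop_map: dict) -> AlleleFreqTable:
    """Tally counted-allele counts and sampled-allele totals per population.

    ``pop_map`` maps every sample id of ``G`` to a population label; an
    unlabeled sample is an error.  Per population and SNP the count is the
    sum of calls over non-missing individuals and the total is twice the
    number of non-missing individuals.
    """
    unlabeled = [s for s in G.samples if s not in pop_map]
    if unlabeled:
        raise ValueError(f"sample {unlabeled[0]!r} has no population label")
    pops = sorted({pop_map[s] for s in G.samples})
    pop_index = {p: i for i, p in enumerate(pops)}
    counts = np.zeros((len(pops), G.n_snps), dtype=np.int64)
    totals = np.zeros_like(counts)
    miss = G.missing_mask()
    for i, s in enumerate(G.samples):
        p = pop_index[pop_map[s]]
        ok = ~miss[i]
        counts[p, ok] += G.calls[i, ok]
        totals[p, ok] += 2
    note = "counted allele = a1 (dataset minor allele when minor_allele_recode applied)"
    return AlleleFreqTable(pops, G.snps.copy(), counts, totals, note)


# ---------------------------------------------------------------------------
# TreeMix frequency format


def write_treemix_freqs(table: AlleleFreqTable, path) -> None:
    """Write the gzip TreeMix frequency file: header of population labels,
    then one line per SNP of ``count,other`` pairs."""
    other = table.totals - table.counts
    with gzip.open(path, "wt") as fh:
        if table.counted_allele_note:
            fh.write(f"# {table.counted_allele_note}\n")
        fh.write(" ".join(str(p) for p in table.populations) + "\n")
        for s in range(table.n_snps):
            fh.write(
                " ".join(
                    f"{table.counts[p, s]},{other[p, s]}"
                    for p in range(table.n_pops)
                )
                + "\n"
            )


def read_treemix_freqs(path, snps: pd.DataFrame | None = None) -> AlleleFreqTable:
    """Read a TreeMix frequency file.

    The format carries no SNP coordinates; pass ``snps`` to attach a map,
    otherwise sequential ids on a single pseudo-chromosome are synthesized
    (sufficient for contiguous-block statistics).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    note = ""
    with opener(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    while lines and lines[0].startswith("#"):
        note = lines.pop(0).lstrip("# ")
    if not lines:
        raise FormatError(f"{path}: empty frequency file")
    pops = lines[0].split()
    counts = np.zeros((len(pops), len(lines) - 1), dtype=np.int64)
    totals = np.zeros_like(counts)
    for s, line in enumerate(lines[1:]):
        pairs = line.split()
        if len(pairs) != len(pops):
            raise FormatError(
                f"{path}: line {s + 2}: {len(pairs)} columns for "
                f"{len(pops)} populations"
            )
        for p, pair in enumerate(pairs):
            try:
                a, b = pair.split(",")
                a, b = int(a), int(b)
            except ValueError:
                raise FormatError(
                    f"{path}: line {s + 2}: bad pair {pair!r}"
                ) from None
            if a < 0 or b < 0:
                raise FormatError(f"{path}: line {s + 2}: negative count {pair!r}")
            counts[p, s] = a
            totals[p, s] = a + b
    if snps is None:
        n = counts.shape[1]
        snps = pd.DataFrame(
            {"id": [f"snp{i}" for i in range(n)], "chrom": 1,
             "pos": np.arange(n, dtype=np.int64) * 1000, "a1": "A", "a2": "B"}
        )
    return AlleleFreqTable(pops, snps, counts, totals, note)
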