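"""Linkage-disequilibrium decay and LD-aware SNP block sizing.

Downstream covariance and f-statistic machinery treats contiguous SNP blocks
as exchangeable units, so the block size must be large enough that
consecutive blocks are effectively unlinked.  This module estimates
within-species LD decay (r^2 against physical distance) and determines the
smallest block size k such that midpoints of consecutive blocks on the same
chromosome are all farther apart than a distance threshold chosen to exceed
the observed extent of LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, UNANCHORED

__all__ = [
    "LDPair",
    "pairwise_ld_r2",
    "ld_decay_bins",
    "block_midpoints",
    "consecutive_midpoint_distances",
    "determine_block_size",
    "block_index",
    "eligible_species",
]


@dataclass(frozen=True)
class LDPair:
    snp_i: str
    snp_j: str
    distance: int  # bp
    r2: float


def pairwise_ld_r2(G: GenotypeMatrix, window_kb: float = 500) -> list[LDPair]:
    """r^2 for all same-chromosome SNP pairs within ``window_kb``.

    r^2 is the squared Pearson correlation of the genotype call vectors over
    samples non-missing at both SNPs (the unphased genotype-correlation
    measure).  Pairs with fewer than 2 informative samples or zero variance
    at either SNP are omitted.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples for LD")
    window = window_kb * 1000
    out: list[LDPair] = []
    snps = G.snps
    calls = G.calls.astype(float)
    calls[G.missing_mask()] = np.nan
    for chrom, idx in snps.groupby("chrom", sort=False).groups.items():
        if chrom == UNANCHORED:
            continue
        idx = np.asarray(idx)
        pos = snps["pos"].to_numpy()[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = int(pos[b] - pos[a])
                if d > window:
                    break
                x, y = calls[:, idx[a]], calls[:, idx[b]]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2:
                    continue
                xo, yo = x[ok], y[ok]
                sx, sy = xo.std(), yo.std()
                if sx == 0 or sy == 0:
                    continue
                r = np.corrcoef(xo, yo)[0, 1]
                out.append(
                    LDPair(snps["id"].iloc[idx[a]], snps["id"].iloc[idx[b]],
                           d, float(r * r))
                )
    return out


def ld_decay_bins(pairs: list[LDPair], bin_size: int = 75) -> list[tuple[float, float]]:
    """Median r^2 in sequential distance-sorted bins of ``bin_size`` pairs.

    Returns per bin ``(mean physical distance in bp, median r^2)``; the last
    bin may hold fewer than ``bin_size`` pairs.
    """
    if not pairs:
        raise ValueError("no LD pairs to bin")
    df = pd.DataFrame({"d": [p.distance for p in pairs], "r2": [p.r2 for p in pairs]})
    df = df.sort_values("d", kind="stable").reset_index(drop=True)
    out = []
    for start in range(0, len(df), bin_size):
        chunk = df.iloc[start : start + bin_size]
        out.append((float(chunk["d"].mean()), float(chunk["r2"].median())))
    return out


def plot_ld_decay(bins, path, species: str | None = None) -> None:
    """Write an LD-decay curve (median r^2 vs mean distance) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dist = [b[0] / 1000 for b in bins]
    med = [b[1] for b in bins]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(dist, med, ".-", ms=4, lw=0.8)
    ax.axhline(0.2, ls=":", color="grey", lw=0.8)
    ax.set_xlabel("mean distance (kb)")
    ax.set_ylabel("median $r^2$")
    if species:
        ax.set_title(species)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def block_index(n_snps: int, k: int) -> np.ndarray:
    """Block id per SNP for contiguous blocks of k over the genome order."""
    return np.arange(n_snps) // k


def block_midpoints(snps: pd.DataFrame, k: int) -> dict:
    """Physical midpoints of contiguous k-SNP blocks, per chromosome.

    Blocks run over the genome-ordered SNP list regardless of chromosome
    boundaries; a block straddling a boundary is split into per-chromosome
    parts and contributes one midpoint per chromosome touched.  The midpoint
    of a part is the middle of its position range, (min + max) / 2.
    """
    if k < 1:
        raise ValueError("block size must be >= 1")
    chroms = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    mid: dict = {}
    for b in range(int(np.ceil(len(snps) / k))):
        sel = slice(b * k, (b + 1) * k)
        for c in pd.unique(chroms[sel]):
            part = pos[sel][chroms[sel] == c]
            mid.setdefault(c, []).append((part.min() + part.max()) / 2)
    return mid


def consecutive_midpoint_distances(snps: pd.DataFrame, k: int) -> np.ndarray:
    """Distances (bp) between consecutive block midpoints within chromosomes."""
    dists = []
    for c, mids in block_midpoints(snps, k).items():
        m = np.sort(np.asarray(mids))
        dists.extend(np.diff(m))
    return np.asarray(dists)


def determine_block_size(
    snps: pd.DataFrame,
    threshold_kb: float = 200,
    start: int = 5,
    step: int = 5,
) -> tuple[int, pd.DataFrame]:
    """Smallest k in {start, start+step, ...} whose consecutive same-chromosome
    block-midpoint distances all exceed ``threshold_kb``.

    Returns ``(k, trace)`` where the trace records, per tested k, the minimum
    midpoint distance (for decay-style plotting).  Raises if no k up to the
    total SNP count satisfies the criterion.
    """
    if threshold_kb <= 0:
        raise ValueError("threshold must be positive")
    threshold = threshold_kb * 1000
    rows = []
    k = start
    while k <= len(snps):
        d = consecutive_midpoint_distances(snps, k)
        min_d = float(d.min()) if len(d) else np.inf
        rows.append({"k": k, "min_distance_bp": min_d, "n_distances": len(d)})
        # vacuous acceptance (no comparable midpoints) is not acceptance
        if len(d) > 0 and min_d > threshold:
            return k, pd.DataFrame(rows)
        k += step
    raise ValueError(
        f"no block size up to {len(snps)} SNPs separates midpoints by "
        f"more than {threshold_kb} kb"
    )


def eligible_species(
    G: GenotypeMatrix, pop_map: dict, min_accessions: int = 10, min_snps: int = 600
) -> list[str]:
    """Species with enough accessions and intraspecific polymorphic SNPs for
    a meaningful LD decay estimate."""
    from .qc_filters import species_subset

    out = []
    for sp in sorted(set(pop_map.values())):
        members = [s for s in G.samples if pop_map.get(s) == sp]
        if len(members) < min_accessions:
            continue
        try:
            sub = species_subset(G, pop_map, sp)
        except ValueError:
            continue
        if sub.n_snps >= min_snps:
            out.append(sp)
    return out
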