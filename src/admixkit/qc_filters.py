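"""Genotype QC cascade: chromosome anchoring, missingness, MAF, exclusions.

The intended pipeline order is: anchoring filter, then sample/SNP
missingness (samples first, SNPs recomputed on the retained samples), then
minor-allele-frequency.  All ">threshold" rules use strict inequality, so a
sample or SNP sitting exactly on the threshold is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "filter_anchored_snps",
    "filter_missingness",
    "filter_maf",
    "apply_exclusion_list",
    "species_subset",
    "qc_pipeline",
]


@dataclass
class FilterReport:
    removed_samples: list = field(default_factory=list)
    removed_snps: list = field(default_factory=list)


def filter_anchored_snps(G: GenotypeMatrix, chrom_range=range(1, 20)) -> GenotypeMatrix:
    """Keep only SNPs anchored to an integer chromosome in ``chrom_range``."""
    keep = np.flatnonzero(G.anchored_mask(chrom_range))
    return G.take_snps(keep)


def filter_missingness(
    G: GenotypeMatrix,
    sample_max: float = 0.2,
    snp_max: float = 0.2,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Drop samples, then SNPs, whose missing fraction strictly exceeds the
    threshold; SNP missingness is computed on the retained samples only."""
    if not (0 <= sample_max <= 1 and 0 <= snp_max <= 1):
        raise ValueError("missingness thresholds must lie in [0, 1]")
    miss = G.missing_mask()
    keep_samples = np.flatnonzero(miss.mean(axis=1) <= sample_max)
    if report is not None:
        report.removed_samples += [
            G.samples[i] for i in range(G.n_samples) if i not in set(keep_samples)
        ]
    G = G.take_samples(keep_samples)
    snp_miss = G.missing_mask().mean(axis=0) if G.n_samples else np.ones(G.n_snps)
    keep_snps = np.flatnonzero(snp_miss <= snp_max)
    if report is not None:
        dropped = set(range(G.n_snps)) - set(keep_snps)
        report.removed_snps += [G.snps["id"].iloc[j] for j in sorted(dropped)]
    G = G.take_snps(keep_snps)
    if G.n_samples == 0 or G.n_snps == 0:
        raise ValueError("all data filtered")
    return G


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Remove SNPs with minor allele frequency strictly below ``min_maf``.

    MAF is computed over non-missing calls; SNPs with no observed calls
    count as MAF 0 and are removed whenever ``min_maf > 0``.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    miss = G.missing_mask()
    n_obs = (~miss).sum(axis=0)
    counted = np.where(miss, 0, G.calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, counted / np.maximum(2 * n_obs, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    maf[n_obs == 0] = 0.0
    return G.take_snps(np.flatnonzero(maf >= min_maf))


def apply_exclusion_list(G: GenotypeMatrix, sample_ids) -> GenotypeMatrix:
    """Remove the listed samples; ids absent from the matrix are warned about."""
    wanted = set(sample_ids)
    present = set(G.samples)
    for sid in sorted(wanted - present):
        logger.warning("exclusion list id %r not present in dataset", sid)
    keep = [i for i, s in enumerate(G.samples) if s not in wanted]
    return G.take_samples(keep)


def species_subset(
    G: GenotypeMatrix,
    pop_map: dict,
    species: str,
    mind: float = 0.2,
    maf: float = 0.01,
) -> GenotypeMatrix:
    """Restrict to one species and re-filter within the subset.

    Mirrors a per-species PLINK pass: sample missingness (``--mind``) applied
    to the subset's samples, then MAF (``--maf``) recomputed within the
    subset.  SNP-level missingness is not re-applied here.
    """
    members = [i for i, s in enumerate(G.samples) if pop_map.get(s) == species]
    if not members:
        raise ValueError(f"species {species!r} not present in population map")
    sub = G.take_samples(members)
    miss = sub.missing_mask().mean(axis=1)
    sub = sub.take_samples(np.flatnonzero(miss <= mind))
    if sub.n_samples == 0:
        raise ValueError(f"species {species!r}: all samples filtered")
    return filter_maf(sub, maf)


def qc_pipeline(
    G: GenotypeMatrix,
    exclude=(),
    sample_max: float = 0.2,
    snp_max: float = 0.2,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, FilterReport]:
    """The full cleaning cascade: exclusions, anchoring, missingness, MAF."""
    report = FilterReport()
    G = apply_exclusion_list(G, exclude)
    G = filter_anchored_snps(G)
    G = filter_missingness(G, sample_max, snp_max, report)
    G = filter_maf(G, min_maf)
    return G, report
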