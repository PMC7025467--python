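"""Block-bootstrap support for migration edges (MS and MS_E indices).

TreeMix-style jackknife p-values for migration weights resample subsets of
the data; the migration-support index instead asks how often a bootstrap
replicate of the SNP blocks, refitted from scratch, recovers an edge
matching the reference edge.  MS uses strict matching (origin and
destination clades identical); MS_E relaxes each endpoint to containment
(one clade a subset of the other), which rescues edges whose attachment
wanders within a complex group across replicates.  Both are percentages of
converged replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import AlleleFreqTable
from .graphfit import FitReport

__all__ = [
    "MigrationEdgeSummary",
    "bootstrap_block_resample",
    "edge_match",
    "migration_support",
    "summarize_migrations",
]


@dataclass
class MigrationEdgeSummary:
    label: str
    origin_tips: frozenset
    dest_tips: frozenset
    n_runs: int
    mean_weight: float
    jackknife_weight: float | None
    se: float | None
    p: float | None
    ms: int | None = None
    ms_e: int | None = None


def bootstrap_block_resample(
    table: AlleleFreqTable, block: int = 20, seed=None
) -> AlleleFreqTable:
    """Resample contiguous ``block``-SNP blocks with replacement.

    SNPs are partitioned into contiguous blocks in genome order (the final
    short block is its own unit); blocks are drawn with replacement until
    the original block count is reached and concatenated preserving
    within-block order.  Deterministic for a fixed seed.
    """
    if block < 1:
        raise ValueError("block size must be >= 1")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(table.n_snps / block))
    draw = rng.integers(0, n_blocks, size=n_blocks)
    idx = np.concatenate([
        np.arange(b * block, min((b + 1) * block, table.n_snps)) for b in draw
    ])
    return table.take_snps(idx)


def edge_match(observed, reference, mode: str = "strict") -> bool:
    """Does an observed migration edge match a reference edge?

    Edges are ``(origin tip-set, destination tip-set)`` pairs (orientation is
    inherent: origin is the source of gene flow).  ``strict``: both tip-sets
    equal.  ``extended``: at each endpoint one set contains the other
    (non-strict containment).
    """
    (oo, od), (ro, rd) = observed, reference
    oo, od, ro, rd = map(frozenset, (oo, od, ro, rd))
    if mode == "strict":
        return oo == ro and od == rd
    if mode == "extended":
        return ((oo <= ro or ro <= oo) and (od <= rd or rd <= od))
    raise ValueError(f"unknown mode {mode!r}")


def _edges_of(report: FitReport):
    return [(info.origin_tips, info.dest_tips) for info in report.migrations]


def migration_support(
    reference: FitReport, replicate_reports, mode: str = "strict"
) -> list[int]:
    """Percentage of replicates containing a matching edge, per reference edge."""
    replicate_reports = list(replicate_reports)
    if not replicate_reports:
        raise ValueError("no bootstrap replicates")
    rep_edges = [_edges_of(r) for r in replicate_reports]
    out = []
    for ref in _edges_of(reference):
        hits = sum(
            any(edge_match(obs, ref, mode) for obs in edges)
            for edges in rep_edges
        )
        out.append(round(100 * hits / len(rep_edges)))
    return out


def summarize_migrations(
    final_runs: list[FitReport],
    bootstrap_reports=None,
    best_run: int = 0,
) -> list[MigrationEdgeSummary]:
    """Group equivalent migration edges across final runs into a summary.

    Edges are grouped by strict matching; each group reports the number of
    runs containing it (N), the mean weight across those runs, and the
    jackknife weight/SE/p from the designated best run.  When bootstrap
    replicate fits are supplied, MS (strict) and MS_E (extended) percentages
    are attached.
    """
    if not final_runs:
        raise ValueError("no runs to summarize")
    groups: list[dict] = []
    for run_i, rep in enumerate(final_runs):
        for info in rep.migrations:
            edge = (info.origin_tips, info.dest_tips)
            for grp in groups:
                if edge_match(edge, grp["edge"], "strict"):
                    grp["weights"].append(info.weight)
                    grp["runs"].add(run_i)
                    if run_i == best_run:
                        grp["best"] = info
                    break
            else:
                groups.append({
                    "edge": edge, "weights": [info.weight],
                    "runs": {run_i},
                    "best": info if run_i == best_run else None,
                })
    groups.sort(key=lambda g: -len(g["runs"]))
    summaries = []
    for label, grp in zip(_edge_labels(), groups):
        best = grp["best"]
        summaries.append(MigrationEdgeSummary(
            label=label,
            origin_tips=grp["edge"][0],
            dest_tips=grp["edge"][1],
            n_runs=len(grp["runs"]),
            mean_weight=float(np.mean(grp["weights"])),
            jackknife_weight=best.jackknife_weight if best else None,
            se=best.se if best else None,
            p=best.p if best else None,
        ))
    if bootstrap_reports is not None:
        ref = final_runs[best_run]
        ms = migration_support(ref, bootstrap_reports, "strict")
        ms_e = migration_support(ref, bootstrap_reports, "extended")
        by_edge = {(i.origin_tips, i.dest_tips): k
                   for k, i in enumerate(ref.migrations)}
        for s in summaries:
            k = by_edge.get((s.origin_tips, s.dest_tips))
            if k is not None:
                s.ms, s.ms_e = ms[k], ms_e[k]
    return summaries


def _edge_labels():
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)
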