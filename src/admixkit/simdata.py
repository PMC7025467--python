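"""Synthetic admixture-graph data: drift frequencies, genotypes, scenarios.

The generator draws a root allele frequency per SNP, evolves it down a
rooted tree by Gaussian drift steps (variance = branch length x p0(1 - p0),
clipped to [0, 1]), mixes frequencies at migration junctions, then samples
diploid genotypes binomially with configurable missingness and optional
short-range LD (SNPs within a block share a perturbed latent frequency).
It emulates the statistical structure of a SNP-array study of wild-grape
species -- a few dozen populations of 2-40 diploids, thousands of biallelic
SNPs on 19 chromosomes -- without coalescent machinery: no recombination
map, no selection, no mutation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import MISSING, AlleleFreqTable, GenotypeMatrix
from .graphfit import AdmixtureGraph

__all__ = [
    "SimSpec",
    "simulate_frequencies",
    "simulate_genotypes",
    "sample_allele_freqs",
    "random_tree",
    "paper_like_scenario",
]


@dataclass
class SimSpec:
    """Study conditions for one synthetic dataset."""

    graph: AdmixtureGraph
    n_snps: int = 4000
    n_chromosomes: int = 19
    chrom_length_bp: int = 25_000_000
    root_freq: tuple = ("uniform", 0.05, 0.95)  # or ("beta", a, b)
    samples_per_pop: dict | int = 20
    missing_rate: float = 0.0
    ld_block_snps: int = 1       # 1 = independent SNPs
    ld_rho: float = 0.0          # within-block correlation strength
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        for _, _, d in self.graph.g.edges(data=True):
            if d.get("kind", "tree") == "tree" and d["length"] < 0:
                raise ValueError("drift branch lengths must be >= 0")

    def n_samples(self, pop) -> int:
        if isinstance(self.samples_per_pop, dict):
            return self.samples_per_pop[pop]
        return int(self.samples_per_pop)


def _draw_root_freqs(spec: SimSpec, rng) -> np.ndarray:
    kind, *params = spec.root_freq
    if kind == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=spec.n_snps)
    if kind == "beta":
        a, b = params
        return rng.beta(a, b, size=spec.n_snps)
    raise ValueError(f"unknown root frequency distribution {kind!r}")


def _snp_map(spec: SimSpec, rng) -> pd.DataFrame:
    chrom = rng.integers(1, spec.n_chromosomes + 1, size=spec.n_snps)
    pos = rng.integers(1, spec.chrom_length_bp, size=spec.n_snps)
    df = pd.DataFrame({
        "id": [f"snp{i}" for i in range(spec.n_snps)],
        "chrom": chrom, "pos": pos, "a1": "A", "a2": "B",
    })
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df["id"] = [f"snp{i}" for i in range(spec.n_snps)]  # ids in genome order
    return df


def simulate_frequencies(spec: SimSpec):
    """Latent population allele frequencies under drift on the graph.

    Returns ``(freqs, snp_map, clip_fraction)`` with ``freqs`` a dict
    population -> array of n_snps frequencies.  ``clip_fraction`` is the
    fraction of drift steps truncated at the [0, 1] boundary; the Gaussian
    approximation is trusted only when this stays small.
    """
    rng = np.random.default_rng(spec.seed)
    p0 = _draw_root_freqs(spec, rng)
    het = p0 * (1 - p0)
    g = spec.graph.g
    node_freq = {spec.graph.root: p0}
    clipped = total_steps = 0
    for node in nx.topological_sort(g):
        if node == spec.graph.root:
            continue
        mig_in = [(u, d["weight"]) for u, _, d in g.in_edges(node, data=True)
                  if d.get("kind") == "migration"]
        tree_in = [(u, d["length"]) for u, _, d in g.in_edges(node, data=True)
                   if d.get("kind", "tree") == "tree"]
        w_mig = sum(w for _, w in mig_in)
        f = np.zeros(spec.n_snps)
        for u, w in mig_in:
            f += w * node_freq[u]
        if tree_in:
            ((parent, length),) = tree_in
            step = node_freq[parent] + rng.normal(
                0.0, np.sqrt(length * het), size=spec.n_snps)
            clipped += int(((step < 0) | (step > 1)).sum())
            total_steps += spec.n_snps
            f += (1 - w_mig) * np.clip(step, 0.0, 1.0)
        node_freq[node] = f
    tips = spec.graph.tips()
    freqs = {t: node_freq[t] for t in tips}
    snp_map = _snp_map(spec, rng)
    clip_fraction = clipped / total_steps if total_steps else 0.0
    return freqs, snp_map, clip_fraction


def simulate_genotypes(freqs: dict, spec: SimSpec, snp_map=None) -> tuple:
    """Diploid genotypes from latent frequencies.

    Returns ``(GenotypeMatrix, pop_map)``.  Calls are Binomial(2, p); with
    LD emulation on (``ld_block_snps > 1``) SNPs within a block share one
    latent draw perturbed by N(0, (1 - rho) * p(1-p) * 0.01), giving decaying
    within-block genotype correlation.  Missingness is i.i.d.
    """
    rng = np.random.default_rng(
        None if spec.seed is None else spec.seed + 1)
    if snp_map is None:
        snp_map = _snp_map(spec, rng)
    samples, rows, pop_map = [], [], {}
    for pop in sorted(freqs):
        p = np.asarray(freqs[pop])
        n = spec.n_samples(pop)
        if n < 1:
            raise ValueError(f"population {pop}: need >= 1 sample")
        if spec.ld_block_snps > 1:
            # per-individual shared latent per block: SNPs in a block draw
            # their copies from a common perturbed frequency, giving
            # within-block genotype correlation ~ld_rho that vanishes
            # across block boundaries
            nb = int(np.ceil(len(p) / spec.ld_block_snps))
            sd = 0.5 * np.sqrt(p * (1 - p))
            for i in range(n):
                anchor = np.repeat(
                    rng.normal(0, 1, size=nb), spec.ld_block_snps)[: len(p)]
                jitter = rng.normal(0, 1, size=len(p))
                z = (np.sqrt(spec.ld_rho) * anchor
                     + np.sqrt(1 - spec.ld_rho) * jitter)
                pp = np.clip(p + sd * z, 0, 1)
                rows.append(rng.binomial(2, pp))
                samples.append(f"{pop}_{i}")
                pop_map[f"{pop}_{i}"] = pop
        else:
            calls = rng.binomial(2, p[None, :], size=(n, len(p)))
            for i in range(n):
                rows.append(calls[i])
                samples.append(f"{pop}_{i}")
                pop_map[f"{pop}_{i}"] = pop
    calls = np.vstack(rows).astype(np.int8)
    if spec.missing_rate > 0:
        calls[rng.random(calls.shape) < spec.missing_rate] = MISSING
    return GenotypeMatrix(samples, snp_map.copy(), calls), pop_map


def sample_allele_freqs(freqs: dict, spec: SimSpec, snp_map=None) -> AlleleFreqTable:
    """AlleleFreqTable by binomial sampling of alleles (bypasses the
    per-individual genotype matrix; equivalent count distribution when LD
    and missingness are off)."""
    rng = np.random.default_rng(
        None if spec.seed is None else spec.seed + 1)
    pops = sorted(freqs)
    if snp_map is None:
        snp_map = _snp_map(spec, rng)
    n_snps = len(next(iter(freqs.values())))
    counts = np.zeros((len(pops), n_snps), dtype=np.int64)
    totals = np.zeros_like(counts)
    for i, pop in enumerate(pops):
        n_alleles = 2 * spec.n_samples(pop)
        counts[i] = rng.binomial(n_alleles, np.asarray(freqs[pop]))
        totals[i] = n_alleles
    return AlleleFreqTable(pops, snp_map, counts, totals)


def random_tree(
    tip_names, rng, branch_scale: float = 0.02, min_length: float = 0.2
) -> AdmixtureGraph:
    """Random rooted binary tree with exponential-ish drift branch lengths.

    ``branch_scale`` sets the mean drift per branch; ``min_length`` (as a
    fraction of the scale) keeps internal branches resolvable.
    """
    tips = list(tip_names)
    if len(tips) < 2:
        raise ValueError("need >= 2 tips")
    g = nx.DiGraph()

    def draw():
        return float(branch_scale * (min_length + rng.exponential(1.0)))

    nodes = list(tips)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = AdmixtureGraph._new_node()
        g.add_edge(parent, a, kind="tree", length=draw())
        g.add_edge(parent, b, kind="tree", length=draw())
        nodes = [n for n in nodes if n not in (a, b)] + [parent]
    root = AdmixtureGraph._new_node()
    for n in nodes:
        g.add_edge(root, n, kind="tree", length=draw())
    return AdmixtureGraph(g, root)


def tip_parent(graph: AdmixtureGraph, tip):
    (p,) = [u for u, _, d in graph.g.in_edges(tip, data=True)
            if d.get("kind", "tree") == "tree"]
    return p


def random_graph_with_migration(
    n_tips: int, rng, w: float = 0.4,
    branch_scale: float = 0.02, outgroup: str = "out",
):
    """Random rooted tree plus one tip-to-tip migration edge.

    The outgroup gets an elongated pendant branch for unambiguous rooting;
    source and destination are non-sister ingroup tips, so the true edge has
    singleton origin and destination clades.  Returns
    ``(graph, (origin_tips, dest_tips), weight)``.
    """
    tips = [f"t{i}" for i in range(n_tips - 1)] + [outgroup]
    graph = random_tree(tips, rng, branch_scale=branch_scale)
    p = tip_parent(graph, outgroup)
    graph.g.edges[p, outgroup]["length"] = branch_scale * 6
    ingroup = [t for t in tips if t != outgroup]
    while True:
        src, dst = rng.choice(ingroup, size=2, replace=False)
        if tip_parent(graph, src) == tip_parent(graph, dst):
            continue  # sisters: migration indistinguishable from topology
        se = (tip_parent(graph, src), src)
        de = (tip_parent(graph, dst), dst)
        cand = graph.copy()
        try:
            key = cand.add_migration(se, de, w)
            cand.validate()
        except ValueError:
            continue
        edge = (cand.subtree_tips(key[0]), cand.subtree_tips(key[1]))
        return cand, edge, w


def balanced_tree(n_tips: int = 8, branch: float = 0.02) -> AdmixtureGraph:
    """Balanced binary tree (n_tips a power of two) with equal drift
    branches; tips named t0..t{n-1} in left-to-right order."""
    if n_tips & (n_tips - 1):
        raise ValueError("n_tips must be a power of two")
    g = nx.DiGraph()
    level = [f"t{i}" for i in range(n_tips)]
    counter = 0
    while len(level) > 1:
        nxt = []
        for i in range(0, len(level), 2):
            parent = f"_b{counter}"
            counter += 1
            g.add_edge(parent, level[i], kind="tree", length=branch)
            g.add_edge(parent, level[i + 1], kind="tree", length=branch)
            nxt.append(parent)
        level = nxt
    return AdmixtureGraph(g, level[0])


def admixture_f3_scenario(parent_drift: float = 0.025,
                          post_drift: float = 0.005) -> AdmixtureGraph:
    """Benchmark for the admixture f3 test.

    Two parents Y and W diverge by 2 x ``parent_drift``; X is a 50/50 mix of
    the two parent lineages at the ends of their branches with
    ``post_drift`` of its own subsequent drift; C is a non-admixed control
    splitting from Y's lineage shortly before the present.
    """
    g = nx.DiGraph()
    g.add_edge("R", "_aY", kind="tree", length=parent_drift)
    g.add_edge("R", "_aW", kind="tree", length=parent_drift)
    g.add_edge("_aY", "_aC", kind="tree", length=0.0)
    g.add_edge("_aC", "Y", kind="tree", length=1e-4)
    g.add_edge("_aC", "C", kind="tree", length=post_drift)
    g.add_edge("_aW", "W", kind="tree", length=1e-4)
    # junction J mixes the two parent lineages; X drifts after admixture
    g.add_edge("_aY", "_J", kind="tree", length=0.0)
    g.add_edge("_aW", "_J", kind="migration", weight=0.5)
    g.add_edge("_J", "X", kind="tree", length=post_drift)
    return AdmixtureGraph(g, "R")


def six_tip_migration_scenario(w: float = 0.4):
    """Fixed six-tip benchmark graph with one migration edge.

    Topology (out,((t0,t1),(t2,(t3,t4)))) with internal branches 0.02 and
    pendant branches 0.03 drift units (outgroup pendant 0.12), plus a
    migration t1 -> t3 of weight ``w`` attached at the midpoints of the two
    pendant edges.  Branch lengths are large enough that every split and the
    weight are well identified at a few thousand SNPs; replicate datasets
    vary the drift and sampling randomness, not the graph.  Returns
    ``(graph, (origin_tips, dest_tips), w)``.
    """
    g = nx.DiGraph()
    edges = [
        ("R", "out", 0.12), ("R", "i1", 0.02),
        ("i1", "i2", 0.02), ("i1", "i3", 0.02),
        ("i2", "t0", 0.03), ("i2", "t1", 0.03),
        ("i3", "t2", 0.03), ("i3", "i4", 0.02),
        ("i4", "t3", 0.03), ("i4", "t4", 0.03),
    ]
    for u, v, l in edges:
        g.add_edge(u, v, kind="tree", length=l)
    graph = AdmixtureGraph(g, "R", outgroup="out")
    key = graph.add_migration(("i2", "t1"), ("i4", "t3"), w)
    graph.validate()
    edge = (graph.subtree_tips(key[0]), graph.subtree_tips(key[1]))
    return graph, edge, w


@dataclass
class ScenarioBundle:
    spec: SimSpec
    genotypes: GenotypeMatrix
    pop_map: dict
    true_graph: AdmixtureGraph
    true_freqs: dict = field(repr=False)
    clip_fraction: float = 0.0


def paper_like_scenario(
    seed: int,
    n_pops: int = 31,
    n_snps: int = 4000,
    n_migrations: int = 8,
) -> ScenarioBundle:
    """A canned dataset shaped like the wild-grape study.

    31 ingroup populations plus one outgroup, 2-40 diploids each, ~4,000
    biallelic SNPs on 19 chromosomes, drift on a random tree with
    ``n_migrations`` weighted migration edges (weights uniform in
    [0.14, 0.49]), 5% missingness.  The true graph and latent frequencies
    travel with the data for recovery tests.
    """
    rng = np.random.default_rng(seed)
    names = [f"pop{i:02d}" for i in range(n_pops)] + ["outgroup"]
    tree = random_tree(names, rng, branch_scale=0.02)
    # lengthen the outgroup pendant edge so rooting is unambiguous
    (p,) = [u for u, v in tree.tree_edges() if v == "outgroup"]
    tree.g.edges[p, "outgroup"]["length"] = 0.15
    graph = tree
    edges = [e for e in graph.tree_edges()]
    added = 0
    attempts = 0
    while added < n_migrations and attempts < 50 * n_migrations:
        attempts += 1
        edges = graph.tree_edges()
        se = edges[rng.integers(len(edges))]
        de = edges[rng.integers(len(edges))]
        if se == de or "outgroup" in (se[1], de[1]):
            continue
        w = float(rng.uniform(0.14, 0.49))
        cand = graph.copy()
        try:
            cand.add_migration(se, de, w)
            cand.validate()
        except ValueError:
            continue
        graph = cand
        added += 1
    sizes = {n: int(rng.integers(2, 41)) for n in names}
    spec = SimSpec(
        graph=graph, n_snps=n_snps, samples_per_pop=sizes,
        missing_rate=0.05, seed=int(rng.integers(2**31)),
    )
    freqs, snp_map, clip = simulate_frequencies(spec)
    G, pop_map = simulate_genotypes(freqs, spec, snp_map)
    return ScenarioBundle(spec, G, pop_map, graph, freqs, clip)
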