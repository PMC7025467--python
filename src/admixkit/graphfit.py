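"""Gaussian-drift covariance model and admixture-graph fitting.

Model
-----
Population allele frequencies evolve by drift on a rooted tree: along a
branch of drift length c the frequency performs a Gaussian step with
variance c * p0(1 - p0).  A migration edge with weight w makes the recipient
node's frequency a mixture w * (source) + (1 - w) * (tree parent).  Each
tip's frequency is then a fixed linear combination of per-branch drift
increments, so the (double-centered) covariance of population frequencies is
linear in the branch lengths:

    C = center( U diag(lengths) U^T ),

where U[i, b] is the total ancestry weight with which tip i's lineage
traverses branch b (products of w / (1 - w) factors over migration
junctions), and center(M) = M - rowmean - colmean + grandmean matches the
per-SNP centering applied to the observed frequencies.

Fitting
-------
The observed covariance W_hat is the across-SNP mean of centered frequency
outer products, with per-entry SEs from a delete-one-block jackknife.  A
normal composite log-likelihood over the unique matrix entries scores a
graph; for a fixed topology and migration weights the maximizing branch
lengths solve a nonnegative weighted least-squares problem, and migration
weights are optimized by bounded scalar search.  Topology search is
hill-climbing over nearest-neighbor interchanges (plus optional
subtree-prune-regraft sweeps) from neighbor-joining or random starts;
migration edges are added greedily at the largest positive scaled residual.

This is a re-implementation of the model class, not a port: the composite
likelihood scale is not comparable with TreeMix's printed values, but
topologies, variance explained, edge placements and weights are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .genotype_io import AlleleFreqTable

__all__ = [
    "AdmixtureGraph",
    "CovMatrix",
    "FitReport",
    "covariance_matrix",
    "predicted_covariance",
    "composite_loglik",
    "fit_tree",
    "add_migration_edges",
    "variance_explained",
    "scaled_residuals",
]

W_BOUNDS = (0.001, 0.999)


# ---------------------------------------------------------------------------
# graph container


@dataclass
class AdmixtureGraph:
    """Rooted tree plus weighted directed migration edges.

    ``g`` is a DiGraph whose edges carry ``kind`` ("tree" with ``length`` >= 0,
    or "migration" with ``weight`` in (0, 1)).  Tips are nodes without
    outgoing tree edges; internal nodes (including migration attachment
    points) use reserved ``_``-prefixed names.
    """

    g: nx.DiGraph
    root: str
    outgroup: str | None = None

    def copy(self) -> "AdmixtureGraph":
        return AdmixtureGraph(self.g.copy(), self.root, self.outgroup)

    def tips(self) -> list:
        return sorted(
            n for n in self.g.nodes
            if not any(d.get("kind", "tree") == "tree"
                       for _, _, d in self.g.out_edges(n, data=True))
        )

    def tree_edges(self) -> list:
        return [(u, v) for u, v, d in self.g.edges(data=True)
                if d.get("kind", "tree") == "tree"]

    def migration_edges(self) -> list:
        return [(u, v, d["weight"]) for u, v, d in self.g.edges(data=True)
                if d.get("kind") == "migration"]

    def branch_lengths(self) -> dict:
        return {(u, v): self.g.edges[u, v]["length"] for u, v in self.tree_edges()}

    def set_branch_lengths(self, lengths: dict) -> None:
        for e, l in lengths.items():
            self.g.edges[e]["length"] = float(l)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.g):
            raise ValueError("graph has a directed cycle")
        for u, v, w in self.migration_edges():
            if not (0 < w < 1):
                raise ValueError(f"migration weight {w} outside (0, 1)")
        for v in self.g.nodes:
            win = sum(d["weight"] for _, _, d in self.g.in_edges(v, data=True)
                      if d.get("kind") == "migration")
            if win >= 1:
                raise ValueError(f"node {v}: migration inflow {win} >= 1")

    def subtree_tips(self, node) -> frozenset:
        """Tips reachable from ``node`` through tree edges only."""
        tips, stack = set(), [node]
        tree_children = {
            n: [v for _, v, d in self.g.out_edges(n, data=True)
                if d.get("kind", "tree") == "tree"]
            for n in self.g.nodes
        }
        while stack:
            n = stack.pop()
            kids = tree_children[n]
            if kids:
                stack.extend(kids)
            else:
                tips.add(n)
        return frozenset(tips)

    def migration_clades(self) -> list[tuple[frozenset, frozenset, float]]:
        """(origin tip-set, destination tip-set, weight) per migration edge."""
        return [(self.subtree_tips(u), self.subtree_tips(v), w)
                for u, v, w in self.migration_edges()]

    # -- construction helpers ------------------------------------------------

    _counter = itertools.count()

    @classmethod
    def _new_node(cls) -> str:
        return f"_n{next(cls._counter)}"

    def insert_attachment(self, edge) -> str:
        """Split a tree edge at its midpoint, returning the new node."""
        u, v = edge
        l = self.g.edges[u, v]["length"]
        m = self._new_node()
        self.g.remove_edge(u, v)
        self.g.add_edge(u, m, kind="tree", length=l / 2)
        self.g.add_edge(m, v, kind="tree", length=l / 2)
        return m

    def add_migration(self, src_edge, dst_edge, weight: float) -> tuple:
        """Attach a migration edge between midpoints of two tree edges."""
        s = self.insert_attachment(src_edge)
        d = self.insert_attachment(dst_edge)
        self.g.add_edge(s, d, kind="migration", weight=float(weight))
        if not nx.is_directed_acyclic_graph(self.g):
            raise ValueError("migration edge would create a cycle")
        return (s, d)

    def newick(self, lengths: bool = True, labels: dict | None = None) -> str:
        """Newick of the tree part (migration edges ignored)."""
        labels = labels or {}

        def fmt(n):
            kids = [v for _, v, d in self.g.out_edges(n, data=True)
                    if d.get("kind", "tree") == "tree"]
            if not kids:
                s = str(n)
            else:
                s = "(" + ",".join(fmt(k) for k in kids) + ")" + str(
                    labels.get(n, ""))
            if lengths and n != self.root:
                (p,) = [u for u, _, d in self.g.in_edges(n, data=True)
                        if d.get("kind", "tree") == "tree"]
                s += f":{self.g.edges[p, n]['length']:.6g}"
            return s

        return fmt(self.root) + ";"


def path_coefficients(graph: AdmixtureGraph):
    """Ancestry weight of each tip on each tree branch.

    Returns ``(U, branches, tips)``: U[i, b] is the probability-weighted
    inclusion of branch ``branches[b]`` in the ancestry of ``tips[i]``.
    """
    g = graph.g
    branches = [(u, v) for u, v, d in g.edges(data=True)
                if d.get("kind", "tree") == "tree"]
    b_idx = {e: i for i, e in enumerate(branches)}
    coef = {graph.root: np.zeros(len(branches))}
    for node in nx.topological_sort(g):
        if node == graph.root:
            continue
        mig_in = [(u, d["weight"]) for u, _, d in g.in_edges(node, data=True)
                  if d.get("kind") == "migration"]
        tree_in = [u for u, _, d in g.in_edges(node, data=True)
                   if d.get("kind", "tree") == "tree"]
        w_mig = sum(w for _, w in mig_in)
        a = np.zeros(len(branches))
        for u, w in mig_in:
            a += w * coef[u]
        if tree_in:
            (p,) = tree_in
            inc = coef[p].copy()
            inc[b_idx[(p, node)]] += 1.0
            a += (1 - w_mig) * inc
        coef[node] = a
    tips = graph.tips()
    U = np.vstack([coef[t] for t in tips])
    return U, branches, tips


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(0, keepdims=True) - M.mean(1, keepdims=True) + M.mean()


def predicted_covariance(
    graph: AdmixtureGraph, populations=None, scale: float = 1.0
) -> np.ndarray:
    """Model covariance of centered population frequencies, in the order of
    ``populations`` (default: sorted tips).  ``scale`` multiplies all branch
    lengths (the heterozygosity factor mean p0(1-p0) when comparing with a
    frequency-scale observed covariance)."""
    graph.validate()
    U, branches, tips = path_coefficients(graph)
    lengths = np.array([graph.g.edges[e]["length"] for e in branches])
    V = (U * lengths) @ U.T * scale
    C = _center(V)
    if populations is not None:
        order = [tips.index(p) for p in populations]
        C = C[np.ix_(order, order)]
    return C


# ---------------------------------------------------------------------------
# observed covariance


@dataclass
class CovMatrix:
    """Observed P x P covariance of centered population allele frequencies,
    with per-entry jackknife SEs and per-block sums for downstream
    resampling."""

    populations: list
    W: np.ndarray
    SE: np.ndarray
    n_blocks: int
    block_sums: np.ndarray = field(repr=False)   # (B, P, P)
    block_nsnps: np.ndarray = field(repr=False)  # (B,)

    def delete_block(self, b: int) -> np.ndarray:
        """Leave-one-block-out covariance estimate."""
        n = self.block_nsnps.sum() - self.block_nsnps[b]
        return (self.block_sums.sum(0) - self.block_sums[b]) / n


def covariance_matrix(
    table: AlleleFreqTable, block: int = 20, noss: bool = True
) -> CovMatrix:
    """Sample covariance of population allele frequencies.

    Per usable SNP (every population has data) the frequencies are centered
    by their across-population mean and the outer product accumulated; W is
    the across-SNP mean.  With ``noss=False`` the binomial sampling-noise
    term x(1-x)/(n-1) is subtracted per population (propagated through the
    centering); the default matches TreeMix's ``-noss`` behaviour of leaving
    sample-size effects uncorrected.  SEs are per-entry weighted jackknife
    over contiguous ``block``-SNP blocks.
    """
    if table.n_pops < 3:
        raise ValueError("need at least 3 populations")
    P = table.n_pops
    freqs = table.freqs()
    usable = np.all(table.totals > 0, axis=0)
    if not noss:
        usable &= np.all(table.totals > 1, axis=0)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable SNPs")
    blocks = np.arange(table.n_snps) // block
    X = freqs[:, usable]
    blk = blocks[usable]
    Y = X - X.mean(axis=0, keepdims=True)
    outer = np.einsum("is,js->sij", Y, Y)
    if not noss:
        h = X * (1 - X) / (table.totals[:, usable] - 1)  # (P, S)
        bias = np.zeros_like(outer)
        s_h = h.sum(axis=0)
        for i in range(P):
            bias[:, i, i] += h[i]
            bias[:, i, :] -= h[i, :, None] / P
            bias[:, :, i] -= h[i, :, None] / P
        bias += (s_h / P**2)[:, None, None]
        outer = outer - bias
    ids = np.unique(blk)
    block_sums = np.stack([outer[blk == b].sum(axis=0) for b in ids])
    block_nsnps = np.array([(blk == b).sum() for b in ids])
    n = block_nsnps.sum()
    W = block_sums.sum(axis=0) / n
    if len(ids) < 2:
        raise ValueError("need at least 2 SNP blocks for jackknife SEs")
    loo = (block_sums.sum(axis=0)[None] - block_sums) / (
        n - block_nsnps)[:, None, None]
    B = len(ids)
    hfac = (n / block_nsnps)[:, None, None]
    theta_dot = B * W - ((1 - block_nsnps[:, None, None] / n) * loo).sum(axis=0)
    pseudo = hfac * W - (hfac - 1) * loo
    var = ((pseudo - theta_dot) ** 2 / (hfac - 1)).sum(axis=0) / B
    SE = np.sqrt(np.maximum(var, 1e-300))
    return CovMatrix(list(table.populations), W, SE, B, block_sums, block_nsnps)


# ---------------------------------------------------------------------------
# composite likelihood and branch-length fitting


_UIDX_CACHE: dict = {}

_LOG_2PI = float(np.log(2 * np.pi))


def _uidx(P: int):
    if P not in _UIDX_CACHE:
        _UIDX_CACHE[P] = np.triu_indices(P)
    return _UIDX_CACHE[P]


def _normal_loglik(x, mu, se):
    z = (x - mu) / se
    return float(np.sum(-0.5 * z * z - np.log(se) - 0.5 * _LOG_2PI))


def composite_loglik(W: np.ndarray, SE: np.ndarray, C: np.ndarray) -> float:
    """Normal composite log-likelihood over unique (i <= j) entries."""
    if (SE <= 0).any():
        raise ValueError("SE entries must be positive")
    iu = _uidx(W.shape[0])
    return _normal_loglik(W[iu], C[iu], SE[iu])


def graph_loglik(graph: AdmixtureGraph, cov: CovMatrix) -> float:
    C = predicted_covariance(graph, cov.populations)
    return composite_loglik(cov.W, cov.SE, C)


def _design(U: np.ndarray, P: int) -> np.ndarray:
    """Columns = vec of center(u_b u_b^T) over unique entries, per branch."""
    iu = _uidx(P)
    H = U - U.mean(axis=0, keepdims=True)
    # center(u u^T) = (Hu)(Hu)^T for the double-centering projection
    cols = np.einsum("ib,jb->bij", H, H)
    return cols[:, iu[0], iu[1]].T


def fit_branch_lengths(graph: AdmixtureGraph, cov: CovMatrix):
    """Maximize the composite likelihood over branch lengths (>= 0) for a
    fixed topology and fixed migration weights; returns (graph, loglik)."""
    U, branches, tips = path_coefficients(graph)
    order = [tips.index(p) for p in cov.populations]
    U = U[order]
    P = len(cov.populations)
    iu = _uidx(P)
    wts = 1.0 / cov.SE[iu]
    A = _design(U, P) * wts[:, None]
    y = cov.W[iu] * wts
    lengths, _ = optimize.nnls(A, y)
    graph.set_branch_lengths(dict(zip(branches, lengths)))
    C = _center((U * lengths) @ U.T)
    return graph, composite_loglik(cov.W, cov.SE, C)


# ---------------------------------------------------------------------------
# topology: neighbor joining start, NNI/SPR hill-climb


def _nj_start(W: np.ndarray, populations, rng, noise: float = 0.0):
    """Neighbor-joining tree from drift distances d_ij = Wii + Wjj - 2 Wij."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    P = len(populations)
    d = np.add.outer(np.diag(W), np.diag(W)) - 2 * W
    if noise:
        pert = rng.normal(0, noise * (np.abs(d).mean() + 1e-12), size=d.shape)
        d = d + pert + pert.T
    d = np.maximum(d, 0)
    np.fill_diagonal(d, 0)
    d = (d + d.T) / 2
    tree = nj(DistanceMatrix(d, ids=[str(p) for p in populations]))
    g = nx.DiGraph()
    name_of = {str(p): p for p in populations}

    def build(node, parent_id):
        nid = name_of[node.name] if node.is_tip() else AdmixtureGraph._new_node()
        if parent_id is not None:
            g.add_edge(parent_id, nid, kind="tree",
                       length=max(node.length or 0.0, 0.0))
        for ch in node.children:
            build(ch, nid)
        return nid

    root = build(tree, None)
    return AdmixtureGraph(g, root)


def _random_topology(populations, rng):
    """Random binary tree by sequential tip insertion."""
    pops = list(populations)
    rng.shuffle(pops)
    g = nx.DiGraph()
    root = AdmixtureGraph._new_node()
    g.add_edge(root, pops[0], kind="tree", length=0.01)
    g.add_edge(root, pops[1], kind="tree", length=0.01)
    graph = AdmixtureGraph(g, root)
    for tip in pops[2:]:
        edges = graph.tree_edges()
        u, v = edges[rng.integers(len(edges))]
        m = graph.insert_attachment((u, v))
        g.add_edge(m, tip, kind="tree", length=0.01)
    return graph


def _suppress_degree2(graph: AdmixtureGraph) -> None:
    """Remove internal nodes with a single tree child and no migration role."""
    g = graph.g
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if n == graph.root or not str(n).startswith("_"):
                continue
            if any(d.get("kind") == "migration"
                   for _, _, d in list(g.in_edges(n, data=True))
                   + list(g.out_edges(n, data=True))):
                continue
            kids = [v for _, v, d in g.out_edges(n, data=True)]
            parents = [u for u, _, d in g.in_edges(n, data=True)]
            if len(kids) == 1 and len(parents) == 1:
                l = g.edges[parents[0], n]["length"] + g.edges[n, kids[0]]["length"]
                g.remove_node(n)
                g.add_edge(parents[0], kids[0], kind="tree", length=l)
                changed = True
    # collapse a root with a single child
    while True:
        kids = list(graph.g.successors(graph.root))
        if len(kids) == 1 and str(kids[0]).startswith("_"):
            graph.g.remove_node(graph.root)
            graph.root = kids[0]
        else:
            break


def _nni_moves(graph: AdmixtureGraph):
    """Candidate NNI rearrangements on internal tree edges (pure tree only)."""
    g = graph.g
    moves = []
    for u, v in graph.tree_edges():
        if u == graph.root:
            continue
        v_kids = [x for _, x, d in g.out_edges(v, data=True)]
        if not v_kids:
            continue  # v is a tip
        sibs = [x for _, x, d in g.out_edges(u, data=True) if x != v]
        for s in sibs:
            for c in v_kids:
                moves.append((u, v, s, c))
    return moves


def _apply_nni(graph: AdmixtureGraph, move) -> AdmixtureGraph:
    u, v, s, c = move
    new = graph.copy()
    g = new.g
    ls, lc = g.edges[u, s]["length"], g.edges[v, c]["length"]
    g.remove_edge(u, s)
    g.remove_edge(v, c)
    g.add_edge(v, s, kind="tree", length=ls)
    g.add_edge(u, c, kind="tree", length=lc)
    return new


def _spr_moves(graph: AdmixtureGraph, max_moves: int, rng):
    """Subtree-prune-regraft candidates: (prune edge, regraft edge)."""
    edges = graph.tree_edges()
    cands = []
    for pe in edges:
        if pe[0] == graph.root:
            continue
        below = nx.descendants(graph.g, pe[1]) | {pe[1]}
        for re_ in edges:
            if re_ == pe or re_[0] in below or re_[1] in below or re_[1] == pe[0]:
                continue
            cands.append((pe, re_))
    if len(cands) > max_moves:
        sel = rng.choice(len(cands), size=max_moves, replace=False)
        cands = [cands[i] for i in sel]
    return cands


def _apply_spr(graph: AdmixtureGraph, move) -> AdmixtureGraph:
    (pu, pv), regraft = move
    new = graph.copy()
    g = new.g
    l = g.edges[pu, pv]["length"]
    g.remove_edge(pu, pv)
    _suppress_degree2(new)
    if not new.g.has_edge(*regraft):
        return graph  # regraft edge merged away; skip
    m = new.insert_attachment(regraft)
    new.g.add_edge(m, pv, kind="tree", length=l)
    return new


def _hill_climb(graph: AdmixtureGraph, cov: CovMatrix, rng,
                spr: bool = True, max_spr: int = 60):
    graph, ll = fit_branch_lengths(graph, cov)
    improved = True
    while improved:
        improved = False
        for move in _nni_moves(graph):
            cand = _apply_nni(graph, move)
            cand, cll = fit_branch_lengths(cand, cov)
            if cll > ll + 1e-9:
                graph, ll = cand, cll
                improved = True
                break
        if not improved and spr:
            for move in _spr_moves(graph, max_spr, rng):
                cand = _apply_spr(graph, move)
                if cand is graph:
                    continue
                cand, cll = fit_branch_lengths(cand, cov)
                if cll > ll + 1e-9:
                    graph, ll = cand, cll
                    improved = True
                    break
    return graph, ll


def root_on_outgroup(graph: AdmixtureGraph, outgroup) -> AdmixtureGraph:
    """Reroot the (pure) tree on the outgroup's pendant edge."""
    und = nx.Graph()
    for u, v in graph.tree_edges():
        und.add_edge(u, v, length=graph.g.edges[u, v]["length"])
    # drop the old root if it has degree 2 in the unrooted tree
    if und.degree(graph.root) == 2:
        a, b = list(und.neighbors(graph.root))
        l = und.edges[graph.root, a]["length"] + und.edges[graph.root, b]["length"]
        und.remove_node(graph.root)
        und.add_edge(a, b, length=l)
    (p,) = list(und.neighbors(outgroup))
    l = und.edges[outgroup, p]["length"]
    root = AdmixtureGraph._new_node()
    und.remove_edge(outgroup, p)
    und.add_edge(root, outgroup, length=l / 2)
    und.add_edge(root, p, length=l / 2)
    g = nx.DiGraph()
    for u, v in nx.bfs_edges(und, root):
        g.add_edge(u, v, kind="tree", length=und.edges[u, v]["length"])
    return AdmixtureGraph(g, root, outgroup=outgroup)


def fit_tree(
    cov: CovMatrix,
    outgroup: str,
    n_searches: int = 10,
    seed: int | None = None,
    spr: bool = True,
    random_start_fraction: float = 0.3,
) -> list[tuple[AdmixtureGraph, float]]:
    """Maximum-composite-likelihood trees from independent searches.

    Each search starts from neighbor joining on the drift distances
    (noise-perturbed after the first search, a fraction from random
    topologies) and hill-climbs with NNI (+SPR) accepting likelihood
    improvements.  Results are rooted on the outgroup and sorted by
    log-likelihood, best first.
    """
    if outgroup not in cov.populations:
        raise ValueError(f"outgroup {outgroup!r} not among populations")
    if len(cov.populations) < 4:
        raise ValueError("need at least 4 populations to fit a tree")
    rng = np.random.default_rng(seed)
    results = []
    for s in range(n_searches):
        if s == 0:
            start = _nj_start(cov.W, cov.populations, rng, noise=0.0)
        elif rng.random() < random_start_fraction:
            start = _random_topology(cov.populations, rng)
        else:
            start = _nj_start(cov.W, cov.populations, rng, noise=0.3)
        graph, ll = _hill_climb(start, cov, rng, spr=spr)
        rooted = root_on_outgroup(graph, outgroup)
        rooted, ll = fit_branch_lengths(rooted, cov)
        results.append((rooted, ll))
    results.sort(key=lambda t: -t[1])
    return results


# ---------------------------------------------------------------------------
# migration edges


@dataclass
class MigrationInfo:
    source_edge: tuple
    dest_edge: tuple
    key: tuple           # (src_node, dst_node) in the graph
    weight: float
    origin_tips: frozenset
    dest_tips: frozenset
    jackknife_weight: float | None = None
    se: float | None = None
    p: float | None = None


@dataclass
class FitReport:
    graph: AdmixtureGraph
    loglik: float
    variance_explained: float
    scaled_residuals: np.ndarray
    migrations: list[MigrationInfo] = field(default_factory=list)
    populations: list = field(default_factory=list)


def variance_explained(W: np.ndarray, C: np.ndarray) -> float:
    """1 - SS_resid / SS_total over unique entries, SS_total about the mean."""
    iu = _uidx(W.shape[0])
    w, c = W[iu], C[iu]
    denom = ((w - w.mean()) ** 2).sum()
    if denom == 0:
        raise ValueError("observed covariance is constant")
    return float(1 - ((w - c) ** 2).sum() / denom)


def scaled_residuals(W: np.ndarray, C: np.ndarray, SE: np.ndarray) -> np.ndarray:
    if (SE <= 0).any():
        raise ValueError("SE entries must be positive")
    return (W - C) / SE


def _optimize_weight(graph: AdmixtureGraph, key, cov: CovMatrix,
                     refit_lengths: bool = True) -> tuple[float, float]:
    """Best weight for one migration edge (others fixed); returns (w, loglik).

    Exploits that the ancestry-coefficient matrix U is affine in a single
    migration weight: U(w) = U0 + w (U1 - U0), so the graph is traversed
    only twice regardless of how many weights the scalar search evaluates.
    """
    w_orig = graph.g.edges[key]["weight"]
    graph.g.edges[key]["weight"] = 0.0
    U0, branches, tips = path_coefficients(graph)
    graph.g.edges[key]["weight"] = 1.0
    U1, _, _ = path_coefficients(graph)
    graph.g.edges[key]["weight"] = w_orig
    order = [tips.index(p) for p in cov.populations]
    U0, U1 = U0[order], U1[order]
    dU = U1 - U0
    P = len(cov.populations)
    iu = _uidx(P)
    wts = 1.0 / cov.SE[iu]
    y = cov.W[iu] * wts
    w_obs, se_obs = cov.W[iu], cov.SE[iu]
    lengths_fixed = np.array([graph.g.edges[e]["length"] for e in branches])

    def eval_w(w):
        U = U0 + w * dU
        if refit_lengths:
            A = _design(U, P) * wts[:, None]
            lengths, _ = optimize.nnls(A, y)
        else:
            lengths = lengths_fixed
        C = _center((U * lengths) @ U.T)
        return lengths, _normal_loglik(w_obs, C[iu], se_obs)

    res = optimize.minimize_scalar(lambda w: -eval_w(w)[1], bounds=W_BOUNDS,
                                   method="bounded",
                                   options={"xatol": 1e-3})
    w_best = float(res.x)
    lengths, ll = eval_w(w_best)
    graph.g.edges[key]["weight"] = w_best
    if refit_lengths:
        graph.set_branch_lengths(dict(zip(branches, lengths)))
    return w_best, ll


def _canonicalize_migration(graph: AdmixtureGraph, key, cov: CovMatrix):
    """Re-express a majority migration (w > 0.5) in canonical form.

    A recipient drawing more than half its ancestry through the migration
    edge is the mirror parameterization of the same covariance: the source
    should be the tree parent and the old tree parent the migration source
    with weight 1 - w.  Swapping roles keeps the likelihood and makes
    weights comparable across replicates.
    """
    s, d = key
    w = graph.g.edges[s, d]["weight"]
    if w <= 0.5:
        return graph, key, w
    mig_in = [(u, v) for u, v, dd in graph.g.in_edges(d, data=True)
              if dd.get("kind") == "migration"]
    if len(mig_in) != 1:
        return graph, key, w
    (pd,) = [u for u, _, dd in graph.g.in_edges(d, data=True)
             if dd.get("kind", "tree") == "tree"]
    cand = graph.copy()
    l_pd = cand.g.edges[pd, d]["length"]
    cand.g.remove_edge(s, d)
    cand.g.remove_edge(pd, d)
    cand.g.add_edge(s, d, kind="tree", length=l_pd)
    cand.g.add_edge(pd, d, kind="migration", weight=1 - w)
    if not nx.is_directed_acyclic_graph(cand.g):
        return graph, key, w
    new_key = (pd, d)
    new_w, _ = _optimize_weight(cand, new_key, cov)
    return cand, new_key, new_w


def _suppress_if_plain(graph: AdmixtureGraph, node) -> None:
    """Merge a node left with one tree parent and one tree child and no
    migration role (after surgery); no-op otherwise."""
    g = graph.g
    if node not in g or node == graph.root:
        return
    if any(d.get("kind") == "migration"
           for _, _, d in list(g.in_edges(node, data=True))
           + list(g.out_edges(node, data=True))):
        return
    kids = list(g.successors(node))
    parents = list(g.predecessors(node))
    if len(kids) == 1 and len(parents) == 1:
        l = g.edges[parents[0], node]["length"] + g.edges[node, kids[0]]["length"]
        g.remove_node(node)
        g.add_edge(parents[0], kids[0], kind="tree", length=l)


def _move_dest(graph: AdmixtureGraph, key, cov):
    """Best re-placement of the migration destination (with its subtree)."""
    s, d = key
    cur_w = graph.g.edges[s, d]["weight"]
    base = graph.copy()
    (pd,) = [u for u, _, dd in base.g.in_edges(d, data=True)
             if dd.get("kind", "tree") == "tree"]
    base.g.remove_edge(pd, d)
    _suppress_if_plain(base, pd)
    best = None
    for e in list(base.tree_edges()):
        cand = base.copy()
        m = cand.insert_attachment(e)
        cand.g.add_edge(m, d, kind="tree", length=0.001)
        if not nx.is_directed_acyclic_graph(cand.g):
            continue
        w, ll = _optimize_weight(cand, key, cov)
        if best is None or ll > best[1]:
            best = (cand, ll, key, w)
    return best


def _move_source(graph: AdmixtureGraph, key, cov):
    """Best re-placement of the migration source attachment point."""
    s, d = key
    base = graph.copy()
    base.g.remove_edge(s, d)
    _suppress_if_plain(base, s)
    best = None
    for e in list(base.tree_edges()):
        if e[1] == d:
            continue  # splitting the edge above d would collide with (m, d)
        cand = base.copy()
        m = cand.insert_attachment(e)
        cand.g.add_edge(m, d, kind="migration", weight=0.2)
        if not nx.is_directed_acyclic_graph(cand.g):
            continue
        new_key = (m, d)
        w, ll = _optimize_weight(cand, new_key, cov)
        if best is None or ll > best[1]:
            best = (cand, ll, new_key, w)
    return best


def _refine_endpoints(graph, key, cov, ll, max_rounds: int = 3):
    """Coordinate refinement of one migration edge's two attachment points,
    accepting likelihood improvements, with canonicalization of majority
    (w > 0.5) weights between rounds."""
    w = graph.g.edges[key]["weight"]
    for _ in range(max_rounds):
        improved = False
        for mover in (_move_dest, _move_source):
            got = mover(graph, key, cov)
            if got is not None and got[1] > ll + 1e-6:
                graph, ll, key, w = got
                improved = True
        g2, k2, w2 = _canonicalize_migration(graph, key, cov)
        if k2 != key:
            ll2 = graph_loglik(g2, cov)
            if ll2 > ll - 1e-6:  # same covariance, accept canonical form
                graph, key, w, ll = g2, k2, w2, ll2
                improved = True
        if not improved:
            break
    return graph, key, w, ll


def _root_path_edges(graph: AdmixtureGraph, tip) -> list:
    """Tree edges from the tip up to the root, nearest-tip first."""
    path = []
    node = tip
    while node != graph.root:
        (p,) = [u for u, _, d in graph.g.in_edges(node, data=True)
                if d.get("kind", "tree") == "tree"]
        path.append((p, node))
        node = p
    return path


def add_migration_edges(
    graph: AdmixtureGraph,
    cov: CovMatrix,
    m: int,
    seed: int | None = None,
    beam: int = 8,
    npairs: int = 4,
    compute_pvalues: bool = True,
    init_w: float = 0.05,
) -> FitReport:
    """Add ``m`` migration edges greedily to a fitted tree.

    Each round ranks population pairs by positive scaled residual
    (least-squares fitting smears a migration signal over several entries,
    so the top ``npairs`` pairs are all explored), proposes source and
    destination attachment points along each pair's two root paths (up to
    ``beam`` edges per endpoint, both orientations), optimizes the weight
    (bounded in ``W_BOUNDS``) jointly with branch lengths for each proposal,
    and keeps the likelihood-best.  After all edges the weights are
    re-optimized jointly (coordinate ascent).  Per-edge p-values come from a
    delete-one-block jackknife of the re-estimated weight with the graph
    structure fixed.
    """
    rng = np.random.default_rng(seed)
    graph = graph.copy()
    graph, ll = fit_branch_lengths(graph, cov)
    pops = cov.populations
    edges_added: list[MigrationInfo] = []
    for _ in range(m):
        C = predicted_covariance(graph, pops)
        R = scaled_residuals(cov.W, C, cov.SE)
        iu = np.triu_indices(len(pops), k=1)
        flat = R[iu]
        order = np.argsort(flat)[::-1][:npairs]
        pairs = [(iu[0][o], iu[1][o]) for o in order if flat[o] > 0]
        if not pairs:
            break  # nothing left to explain
        proposals = set()
        for i, j in pairs:
            for src_tip, dst_tip in ((pops[i], pops[j]), (pops[j], pops[i])):
                src_path = _root_path_edges(graph, src_tip)[:beam]
                dst_path = _root_path_edges(graph, dst_tip)[:beam]
                proposals.update(
                    (se_, de) for se_ in src_path for de in dst_path
                    if se_ != de
                )
        # coarse screen: weight grid with branch lengths held fixed
        screened = []
        for se_, de in proposals:
            cand = graph.copy()
            try:
                key = cand.add_migration(se_, de, init_w)
            except ValueError:
                continue
            best_screen = -np.inf
            for w_try in (0.05, 0.2, 0.35, 0.5):
                cand.g.edges[key]["weight"] = w_try
                best_screen = max(best_screen, graph_loglik(cand, cov))
            screened.append((best_screen, se_, de))
        screened.sort(key=lambda t: -t[0])
        optimized = []
        for _, se_, de in screened[:8]:
            cand = graph.copy()
            key = cand.add_migration(se_, de, init_w)
            w, cll = _optimize_weight(cand, key, cov)
            optimized.append((cand, cll, key, w))
        if not optimized:
            break
        optimized.sort(key=lambda t: -t[1])
        best = None
        for cand, cll, key, w in optimized[:5]:
            cand, key, w, cll = _refine_endpoints(cand, key, cov, cll)
            if best is None or cll > best[1]:
                best = (cand, cll, key, w)
        graph, ll, key, w = best
        graph, ll = fit_branch_lengths(graph, cov)
        edges_added.append(MigrationInfo(
            source_edge=None, dest_edge=None, key=key, weight=w,
            origin_tips=graph.subtree_tips(key[0]),
            dest_tips=graph.subtree_tips(key[1]),
        ))
    # joint re-optimization of all weights (two coordinate-ascent sweeps)
    for _ in range(2 if edges_added else 0):
        for info in edges_added:
            info.weight, ll = _optimize_weight(graph, info.key, cov)
    graph, ll = fit_branch_lengths(graph, cov)
    C = predicted_covariance(graph, pops)
    report = FitReport(
        graph=graph, loglik=ll,
        variance_explained=variance_explained(cov.W, C),
        scaled_residuals=scaled_residuals(cov.W, C, cov.SE),
        migrations=edges_added, populations=list(pops),
    )
    if compute_pvalues and edges_added:
        _migration_pvalues(report, cov)
    for info in edges_added:
        info.origin_tips = graph.subtree_tips(info.key[0])
        info.dest_tips = graph.subtree_tips(info.key[1])
    return report


def _migration_pvalues(report: FitReport, cov: CovMatrix) -> None:
    """Jackknife SE/p for each migration weight with fixed graph structure."""
    graph = report.graph
    for info in report.migrations:
        w_hat = info.weight
        loo = np.empty(cov.n_blocks)
        for b in range(cov.n_blocks):
            Wb = cov.delete_block(b)
            sub = CovMatrix(cov.populations, Wb, cov.SE, cov.n_blocks,
                            cov.block_sums, cov.block_nsnps)
            loo[b], _ = _optimize_weight(graph, info.key, cov=sub,
                                         refit_lengths=False)
        graph.g.edges[info.key]["weight"] = w_hat
        nb = cov.block_nsnps.astype(float)
        n = nb.sum()
        B = cov.n_blocks
        h = n / nb
        theta_dot = B * w_hat - ((1 - nb / n) * loo).sum()
        pseudo = h * w_hat - (h - 1) * loo
        var = np.sum((pseudo - theta_dot) ** 2 / (h - 1)) / B
        info.jackknife_weight = float(theta_dot)
        info.se = float(np.sqrt(var))
        z = w_hat / info.se if info.se > 0 else np.inf
        info.p = float(2 * stats.norm.sf(abs(z)))


def tree_fit_report(graph: AdmixtureGraph, cov: CovMatrix) -> FitReport:
    """FitReport for a migration-free (or already-fitted) graph."""
    graph, ll = fit_branch_lengths(graph.copy(), cov)
    C = predicted_covariance(graph, cov.populations)
    return FitReport(
        graph=graph, loglik=ll,
        variance_explained=variance_explained(cov.W, C),
        scaled_residuals=scaled_residuals(cov.W, C, cov.SE),
        migrations=[], populations=list(cov.populations),
    )
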