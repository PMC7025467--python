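"""Tree post-processing: best-tree filtering, Robinson-Foulds, consensus.

Operates on the tree part of :class:`~admixkit.graphfit.AdmixtureGraph`
objects (migration edges and branch lengths are ignored for topology
comparison, matching how replicate ML searches are summarized).
"""

from __future__ import annotations

import networkx as nx

from .graphfit import AdmixtureGraph

__all__ = [
    "bipartitions",
    "rf_distance",
    "strict_consensus",
    "select_best_trees",
    "consensus_with_support",
    "read_newick",
]


def read_newick(source: str) -> AdmixtureGraph:
    """Parse a newick string (or path) into a rooted AdmixtureGraph.

    Internal-node labels are kept as node 'support' attributes; missing
    branch lengths default to 0.
    """
    import os

    import dendropy

    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, schema="newick")
    else:
        tree = dendropy.Tree.get(data=source, schema="newick")
    g = nx.DiGraph()

    def build(node, parent_id):
        if node.is_leaf():
            nid = node.taxon.label if node.taxon else node.label
        else:
            nid = AdmixtureGraph._new_node()
        if parent_id is not None:
            g.add_edge(parent_id, nid, kind="tree",
                       length=float(node.edge.length or 0.0))
        if not node.is_leaf() and node.label is not None:
            g.add_node(nid, support=node.label)
        for ch in node.child_nodes():
            build(ch, nid)
        return nid

    root = build(tree.seed_node, None)
    return AdmixtureGraph(g, root)


def bipartitions(graph: AdmixtureGraph) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each as the frozenset of the
    smaller side (ties broken by sorted-tuple order)."""
    all_tips = graph.subtree_tips(graph.root)
    out = set()
    for u, v in graph.tree_edges():
        side = graph.subtree_tips(v)
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(frozenset(canon))
    return out


def _check_same_tips(t1: AdmixtureGraph, t2: AdmixtureGraph):
    tips1 = t1.subtree_tips(t1.root)
    tips2 = t2.subtree_tips(t2.root)
    if tips1 != tips2:
        raise ValueError(
            f"tip sets differ: {sorted(tips1 ^ tips2)} not shared"
        )
    return tips1


def rf_distance(t1: AdmixtureGraph, t2: AdmixtureGraph) -> int:
    """Unrooted Robinson-Foulds distance: bipartitions in exactly one tree."""
    _check_same_tips(t1, t2)
    return len(bipartitions(t1) ^ bipartitions(t2))


def select_best_trees(graphs_with_loglik, rel_tol: float = 1e-6):
    """Keep trees within ``|max| * rel_tol`` of the best log-likelihood and
    collapse topological duplicates (RF = 0).

    Returns ``(representatives, n_best_pre_dedup)`` where representatives is
    a list of (graph, loglik), one per distinct topology.
    """
    if not graphs_with_loglik:
        raise ValueError("empty tree list")
    best = max(ll for _, ll in graphs_with_loglik)
    cut = best - abs(best) * rel_tol
    kept = [(g, ll) for g, ll in graphs_with_loglik if ll >= cut]
    reps = []
    seen = []
    for g, ll in kept:
        bp = bipartitions(g)
        if bp not in seen:
            seen.append(bp)
            reps.append((g, ll))
    return reps, len(kept)


def _tree_from_splits(tips, splits, support: dict | None = None) -> AdmixtureGraph:
    """Rooted representation of the unrooted tree induced by a compatible
    split set (splits given as tip frozensets nested within ``tips``)."""
    g = nx.DiGraph()
    root = AdmixtureGraph._new_node()
    parent = {t: root for t in tips}
    graph = AdmixtureGraph(g, root)
    for t in tips:
        g.add_edge(root, t, kind="tree", length=1.0)
    # insert larger groups first so smaller ones nest inside them
    for s in sorted(splits, key=len, reverse=True):
        members = sorted(s)
        p = parent[members[0]]
        # children of p whose tip-closure lies inside s
        kids = [v for v in g.successors(p)
                if graph.subtree_tips(v) <= s]
        covered = frozenset().union(*(graph.subtree_tips(v) for v in kids)) \
            if kids else frozenset()
        if covered != frozenset(s):
            continue  # incompatible with what is already placed; skip
        node = AdmixtureGraph._new_node()
        g.add_edge(p, node, kind="tree", length=1.0)
        for v in kids:
            g.remove_edge(p, v)
            g.add_edge(node, v, kind="tree", length=1.0)
        for t in s:
            parent[t] = node
        if support is not None and s in support:
            g.nodes[node]["support"] = support[s]
    return graph


def strict_consensus(trees) -> AdmixtureGraph:
    """Tree containing exactly the bipartitions present in every input."""
    trees = list(trees)
    if not trees:
        raise ValueError("no trees")
    tips = trees[0].subtree_tips(trees[0].root)
    for t in trees[1:]:
        _check_same_tips(trees[0], t)
    common = set.intersection(*(bipartitions(t) for t in trees))
    return _tree_from_splits(sorted(tips), common)


def consensus_with_support(reference: AdmixtureGraph, replicate_trees):
    """Annotate the reference tree's bipartitions with the percentage of
    replicate trees containing them (bootstrap node support)."""
    reps = [bipartitions(t) for t in replicate_trees]
    if not reps:
        raise ValueError("no replicate trees")
    tips = reference.subtree_tips(reference.root)
    ref_bp = bipartitions(reference)
    support = {
        bp: round(100 * sum(bp in r for r in reps) / len(reps))
        for bp in ref_bp
    }
    return _tree_from_splits(sorted(tips), ref_bp, support), support
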