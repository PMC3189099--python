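"""Conflict graph of a tree-orientation instance.

Two pairs *conflict* when no single orientation of the tree satisfies both,
which happens exactly when their paths traverse some tree edge in opposite
directions.  The conflict graph G_c has one node per pair and one edge per
conflicting pair of pairs; the pairs left unsatisfied by any orientation
form a vertex cover of G_c, so minimizing unsatisfied weight is exactly
minimum-weight vertex cover on G_c.

Construction is by edge marking: each pair's path stamps every edge it
crosses with its direction (child->parent "up" or parent->child "down"),
and every (down, up) combination on an edge yields a conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Edge, MTOInstance, SourceTargetPair, edge_key, path_arcs, tree_path
from .rooted import RootedTree

__all__ = [
    "ConflictGraph",
    "EdgeLoadIndex",
    "pairs_conflict",
    "build_conflict_graph",
    "reduce_conflict_graph",
]


@dataclass
class ConflictGraph:
    """Simple graph on pair indices; ``weights[i]`` is the pair's weight."""

    nodes: set[int]
    weights: dict[int, float]
    edges: set[tuple[int, int]]  # stored as sorted index pairs
    isolated_removed: bool = False

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {v: set() for v in self.nodes}
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    @property
    def n_c(self) -> int:
        return len(self.nodes)

    @property
    def m_c(self) -> int:
        return len(self.edges)


@dataclass
class EdgeLoadIndex:
    """Per tree edge, the pairs traversing it in each direction.

    Tree edges are keyed by their lower (child) endpoint's canonical edge;
    "down" means parent->child in the rooting, "up" the reverse.  The
    maximum load max(|down| + |up|) over edges is the parameter m_e
    ("maximum edge signal flow").
    """

    down: dict[Edge, list[int]] = field(default_factory=dict)
    up: dict[Edge, list[int]] = field(default_factory=dict)

    def load(self, e: Edge) -> int:
        return len(self.down.get(e, ())) + len(self.up.get(e, ()))

    @property
    def m_e(self) -> int:
        keys = set(self.down) | set(self.up)
        return max((self.load(e) for e in keys), default=0)

    def max_edge(self) -> Edge | None:
        keys = sorted(set(self.down) | set(self.up))
        return max(keys, key=self.load, default=None)


def _directed_edges(rooted: RootedTree, p: SourceTargetPair) -> dict[Edge, tuple[str, str]]:
    return {edge_key(a, b): (a, b) for a, b in path_arcs(tree_path(rooted, p.source, p.target))}


def pairs_conflict(rooted: RootedTree, p: SourceTargetPair, q: SourceTargetPair) -> bool:
    """True iff no orientation satisfies both p and q.

    Equivalently: their paths share an edge traversed in opposite
    directions (necessarily an edge incident on the lower of the two path
    LCAs).
    """
    pe = _directed_edges(rooted, p)
    for a, b in path_arcs(tree_path(rooted, q.source, q.target)):
        arc = pe.get(edge_key(a, b))
        if arc is not None and arc != (a, b):
            return True
    return False


def build_conflict_graph(
    instance: MTOInstance, rooted: RootedTree
) -> tuple[ConflictGraph, EdgeLoadIndex]:
    """Edge-marking construction of the conflict graph plus the edge-load index."""
    load = EdgeLoadIndex()
    for idx, p in enumerate(instance.pairs):
        for a, b in path_arcs(tree_path(rooted, p.source, p.target)):
            e = edge_key(a, b)
            if rooted.parent.get(b) == a:  # traversed parent -> child
                load.down.setdefault(e, []).append(idx)
            else:
                load.up.setdefault(e, []).append(idx)
    edges: set[tuple[int, int]] = set()
    for e in set(load.down) | set(load.up):
        for i in load.down.get(e, ()):
            for j in load.up.get(e, ()):
                if i != j:
                    edges.add((i, j) if i < j else (j, i))
    nodes = set(range(len(instance.pairs)))
    weights = {i: p.weight for i, p in enumerate(instance.pairs)}
    return ConflictGraph(nodes, weights, edges), load


def build_conflict_graph_pairwise(instance: MTOInstance, rooted: RootedTree) -> ConflictGraph:
    """Quadratic all-pairs construction; reference oracle for the edge-marking path."""
    n = len(instance.pairs)
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if pairs_conflict(rooted, instance.pairs[i], instance.pairs[j])
    }
    weights = {i: p.weight for i, p in enumerate(instance.pairs)}
    return ConflictGraph(set(range(n)), weights, edges)


def reduce_conflict_graph(cg: ConflictGraph) -> ConflictGraph:
    """Drop isolated nodes: pairs conflicting with nothing are always satisfiable."""
    touched = {v for e in cg.edges for v in e}
    return ConflictGraph(
        nodes=touched,
        weights={v: cg.weights[v] for v in touched},
        edges=set(cg.edges),
        isolated_removed=True,
    )
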