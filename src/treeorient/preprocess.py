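"""Bridge-block contraction: reduce an arbitrary network to a tree.

The edges of any cycle can be oriented to form a directed cycle, which makes
every 2-edge-connected block strongly connectable.  Contracting each bridge
block (a connected component of the graph after deleting all bridges) to a
single vertex therefore preserves the orientation optimum: the tree vertices
are the blocks, the tree edges are the bridges, and pairs whose endpoints
fall inside one block are satisfiable for free.

:func:`lift_orientation` maps a tree orientation back to the full graph by
strongly orienting every nontrivial block with a DFS (tree arcs downward,
back arcs upward — sound for 2-edge-connected graphs by Robbins' theorem).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model import (
    Edge,
    GraphInstance,
    InstanceError,
    MTOInstance,
    Orientation,
    SourceTargetPair,
    TreeInstance,
    edge_key,
    normalize_pairs,
)

__all__ = ["BlockMapping", "find_bridges", "contract_to_tree", "lift_orientation"]


@dataclass
class BlockMapping:
    """Bookkeeping of the contraction.

    ``block_of`` maps each original vertex to its tree vertex; ``members``
    inverts that map; ``bridge_edges`` maps each tree edge to the original
    bridge it came from.  ``pair_origin`` gives, per contracted pair index,
    the original (normalized) pair indices merged into it, and
    ``auto_satisfied_pairs`` lists original pair indices that became internal
    to a block.
    """

    block_of: dict[str, str]
    members: dict[str, set[str]]
    bridge_edges: dict[Edge, Edge]
    pair_origin: dict[int, list[int]] = field(default_factory=dict)
    auto_satisfied_pairs: list[int] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "block_of": self.block_of,
            "members": {b: sorted(m) for b, m in self.members.items()},
        }


def _as_nx(graph: GraphInstance) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.vertices)
    g.add_edges_from(graph.edges)
    return g


def _require_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise InstanceError("empty graph")
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort()
        raise InstanceError(
            f"graph is disconnected ({len(comps)} components); "
            f"smallest members: {[c[0] for c in comps]}"
        )


def find_bridges(graph: GraphInstance) -> set[Edge]:
    """Edges whose deletion disconnects the graph (classical low-link DFS)."""
    g = _as_nx(graph)
    _require_connected(g)
    return {edge_key(u, v) for u, v in nx.bridges(g)}


def _block_name(members: set[str], taken: set[str]) -> str:
    if len(members) == 1:
        return next(iter(members))
    name = "B" + min(members)
    while name in taken:
        name += "_"
    return name


def contract_to_tree(graph: GraphInstance) -> tuple[MTOInstance, BlockMapping, float]:
    """Contract every bridge block to one tree vertex.

    Returns the tree instance, the mapping, and the total weight of pairs
    that became internal to a block (auto-satisfied by a strong orientation
    of that block).  Pairs are normalized (duplicates merged, s = t dropped)
    before contraction; ``pair_origin`` indices refer to the normalized list.
    """
    g = _as_nx(graph)
    _require_connected(g)
    bridges = {edge_key(u, v) for u, v in nx.bridges(g)}
    residual = g.copy()
    residual.remove_edges_from(bridges)
    blocks = [set(c) for c in nx.connected_components(residual)]
    blocks.sort(key=min)

    # deterministic names: singleton blocks keep their vertex id,
    # nontrivial blocks get "B" + smallest member
    taken = {v for b in blocks if len(b) == 1 for v in b}
    block_of: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for b in blocks:
        name = _block_name(b, taken | set(members))
        members[name] = b
        for v in b:
            block_of[v] = name

    tree_edges: dict[Edge, Edge] = {}
    for u, v in sorted(bridges):
        te = edge_key(block_of[u], block_of[v])
        tree_edges[te] = edge_key(u, v)
    tree = TreeInstance(members.keys(), tree_edges.keys())

    norm_pairs, _ = normalize_pairs(graph.pairs)
    mapped: dict[tuple[str, str], float] = {}
    origin: dict[tuple[str, str], list[int]] = {}
    auto_weight = 0.0
    auto_pairs: list[int] = []
    for idx, p in enumerate(norm_pairs):
        bs, bt = block_of[p.source], block_of[p.target]
        if bs == bt:
            auto_weight += p.weight
            auto_pairs.append(idx)
            continue
        mapped[(bs, bt)] = mapped.get((bs, bt), 0.0) + p.weight
        origin.setdefault((bs, bt), []).append(idx)

    pairs = [SourceTargetPair(s, t, w) for (s, t), w in sorted(mapped.items())]
    mapping = BlockMapping(
        block_of=block_of,
        members=members,
        bridge_edges=tree_edges,
        pair_origin={i: origin[(p.source, p.target)] for i, p in enumerate(pairs)},
        auto_satisfied_pairs=auto_pairs,
    )
    return MTOInstance(tree, pairs), mapping, auto_weight


def _strong_orient_block(g: nx.Graph, block: set[str], orient: Orientation) -> None:
    """DFS orientation of a 2-edge-connected block: discovery arcs forward,
    back arcs from the later-discovered endpoint to the earlier one."""
    sub = g.subgraph(block)
    neighbors = {v: sorted(sub.neighbors(v)) for v in block}
    root = min(block)
    disc: dict[str, int] = {root: 0}
    counter = 0
    tree_edge_keys: set[Edge] = set()
    # cursor-based DFS so that every non-tree edge is a back edge
    stack: list[tuple[str, int]] = [(root, 0)]
    while stack:
        v, i = stack.pop()
        if i < len(neighbors[v]):
            stack.append((v, i + 1))
            u = neighbors[v][i]
            if u not in disc:
                counter += 1
                disc[u] = counter
                tree_edge_keys.add(edge_key(v, u))
                orient.add_arc(v, u)  # spanning-tree arc: downward
                stack.append((u, 0))
    for u, v in sub.edges:
        e = edge_key(u, v)
        if e in tree_edge_keys:
            continue
        a, b = e
        # back edge: orient from descendant (later discovery) to ancestor
        if disc[a] > disc[b]:
            orient.add_arc(a, b)
        else:
            orient.add_arc(b, a)


def lift_orientation(
    graph: GraphInstance, mapping: BlockMapping, tree_orientation: Orientation
) -> Orientation:
    """Lift a tree orientation back to the original graph.

    Bridges inherit the tree arc direction; every nontrivial block is
    strongly oriented, so each pair satisfied on the tree is satisfied in
    the lifted orientation, as is every block-internal pair.
    """
    g = _as_nx(graph)
    lifted = Orientation()
    for tree_edge, orig_edge in mapping.bridge_edges.items():
        if tree_edge not in tree_orientation.arcs:
            raise InstanceError(f"tree orientation is missing bridge {tree_edge}")
        tail_block, head_block = tree_orientation.arcs[tree_edge]
        u, v = orig_edge
        if mapping.block_of[u] == tail_block:
            lifted.add_arc(u, v)
        else:
            lifted.add_arc(v, u)
    for block in mapping.members.values():
        if len(block) > 1:
            _strong_orient_block(g, block, lifted)
    return lifted
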