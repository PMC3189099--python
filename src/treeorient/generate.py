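"""Synthetic instance generators.

Every solver in the package is testable without external network data:
this module produces uniform random labeled trees (Prüfer decoding),
stars, paths, cross-pair-free instances, bounded-edge-load instances,
random connected graphs with cycles, and star instances derived from
directed graphs via the maximum-dicut correspondence (the pairs of a star
instance are exactly the arcs of a digraph, and an orientation of the
star corresponds to a vertex bipartition, so the optimum equals the
maximum directed cut).

All generators take an explicit integer seed and use a private
``random.Random``; the same seed always reproduces the same instance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import product

from .model import Edge, GraphInstance, SourceTargetPair, edge_key

__all__ = [
    "Digraph",
    "gen_instance",
    "gen_connected_graph",
    "gen_digraph",
    "maxdicut_to_star",
    "max_dicut_brute",
]

KINDS = ("tree", "star", "path", "crossfree", "bounded_me")


@dataclass
class Digraph:
    """A simple directed graph: no self-arcs, no parallel arcs."""

    vertices: set[str]
    arcs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.arcs:
            if u == v:
                raise ValueError(f"self-arc on {u!r}")


def _names(n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"v{i:0{width}d}" for i in range(n)]


def _prufer_tree(names: list[str], rng: random.Random) -> set[Edge]:
    """Uniform random labeled tree by Prüfer sequence decoding."""
    n = len(names)
    if n == 1:
        return set()
    if n == 2:
        return {edge_key(names[0], names[1])}
    seq = [rng.randrange(n) for _ in range(n - 2)]
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges: set[Edge] = set()
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.add(edge_key(names[leaf], names[x]))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.add(edge_key(names[u], names[v]))
    return edges


def _draw_weight(rng: random.Random, weighted: bool) -> float:
    return float(rng.randint(1, 10)) if weighted else 1.0


def _sample_pairs(
    candidates: list[tuple[str, str]],
    n_pairs: int,
    rng: random.Random,
    weighted: bool,
    accept=None,
) -> list[SourceTargetPair]:
    used: set[tuple[str, str]] = set()
    pairs: list[SourceTargetPair] = []
    tries = 0
    limit = 500 * max(n_pairs, 1)
    while len(pairs) < n_pairs:
        tries += 1
        if tries > limit:
            raise ValueError(
                f"could not draw {n_pairs} admissible pairs after {limit} attempts"
            )
        s, t = candidates[rng.randrange(len(candidates))]
        if (s, t) in used:
            continue
        if accept is not None and not accept(s, t):
            continue
        used.add((s, t))
        pairs.append(SourceTargetPair(s, t, _draw_weight(rng, weighted)))
    return pairs


def gen_instance(
    kind: str,
    n: int,
    n_pairs: int,
    seed: int,
    me_cap: int | None = None,
    weighted: bool = False,
) -> GraphInstance:
    """Generate a deterministic tree instance of the requested family.

    ``tree``: uniform random labeled tree, pairs uniform over distinct
    ordered vertex pairs.  ``star``: center v0 with n-1 leaves, pairs among
    leaves.  ``path``: the n-vertex path.  ``crossfree``: random tree
    rooted at v0 with every pair drawn along an ancestor line, direction
    uniform.  ``bounded_me``: random tree with pairs rejection-sampled so
    no edge carries more than ``me_cap`` paths.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}; choose one of {KINDS}")
    if n < 2:
        raise ValueError("n must be at least 2")
    if n_pairs < 0:
        raise ValueError("n_pairs must be nonnegative")
    rng = random.Random(seed)
    names = _names(n)

    if kind == "star":
        edges = {edge_key(names[0], leaf) for leaf in names[1:]}
        cands = [(s, t) for s in names[1:] for t in names[1:] if s != t]
        pairs = _sample_pairs(cands, n_pairs, rng, weighted)
        return GraphInstance(set(names), edges, pairs)

    if kind == "path":
        edges = {edge_key(names[i], names[i + 1]) for i in range(n - 1)}
        cands = [(s, t) for s in names for t in names if s != t]
        pairs = _sample_pairs(cands, n_pairs, rng, weighted)
        return GraphInstance(set(names), edges, pairs)

    edges = _prufer_tree(names, rng)

    if kind == "tree":
        cands = [(s, t) for s in names for t in names if s != t]
        pairs = _sample_pairs(cands, n_pairs, rng, weighted)
        return GraphInstance(set(names), edges, pairs)

    # adjacency for the remaining kinds
    adj: dict[str, list[str]] = {v: [] for v in names}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)

    if kind == "crossfree":
        root = names[0]
        # ancestor line of each vertex under the fixed root
        parent: dict[str, str | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in parent:
                    parent[y] = x
                    order.append(y)
                    stack.append(y)
        lines: list[tuple[str, str]] = []
        for v in names:
            a = parent[v]
            while a is not None:
                lines.append((v, a))  # both directions covered below
                lines.append((a, v))
                a = parent[a]
        if not lines:
            raise ValueError("crossfree generation needs n >= 2")
        pairs = _sample_pairs(lines, n_pairs, rng, weighted)
        return GraphInstance(set(names), edges, pairs)

    # bounded_me
    if me_cap is None or me_cap < 1:
        raise ValueError("bounded_me requires me_cap >= 1")
    load: dict[Edge, int] = {e: 0 for e in edges}
    parent = {names[0]: None}
    stack = [names[0]]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in parent:
                parent[y] = x
                stack.append(y)
    depth = {names[0]: 0}
    for v in names:
        chain = []
        x = v
        while x not in depth:
            chain.append(x)
            x = parent[x]  # type: ignore[index]
        d = depth[x]
        for y in reversed(chain):
            d += 1
            depth[y] = d

    def path_edges(s: str, t: str) -> list[Edge]:
        a, b = s, t
        out = []
        while a != b:
            if depth[a] < depth[b]:
                out.append(edge_key(b, parent[b]))  # type: ignore[arg-type]
                b = parent[b]  # type: ignore[assignment]
            else:
                out.append(edge_key(a, parent[a]))  # type: ignore[arg-type]
                a = parent[a]  # type: ignore[assignment]
        return out

    def accept(s: str, t: str) -> bool:
        pe = path_edges(s, t)
        if any(load[e] + 1 > me_cap for e in pe):
            return False
        for e in pe:
            load[e] += 1
        return True

    cands = [(s, t) for s in names for t in names if s != t]
    pairs = _sample_pairs(cands, n_pairs, rng, weighted, accept=accept)
    return GraphInstance(set(names), edges, pairs)


def gen_connected_graph(
    n: int, extra_edges: int, n_pairs: int, seed: int, weighted: bool = False
) -> GraphInstance:
    """Random connected graph: a random tree plus ``extra_edges`` chords."""
    rng = random.Random(seed)
    names = _names(n)
    edges = set(_prufer_tree(names, rng))
    non_edges = [
        edge_key(a, b)
        for i, a in enumerate(names)
        for b in names[i + 1:]
        if edge_key(a, b) not in edges
    ]
    rng.shuffle(non_edges)
    edges.update(non_edges[:extra_edges])
    cands = [(s, t) for s in names for t in names if s != t]
    pairs = _sample_pairs(cands, n_pairs, rng, weighted)
    return GraphInstance(set(names), edges, pairs)


def gen_digraph(n: int, n_arcs: int, seed: int) -> Digraph:
    """Random simple digraph on n vertices with up to ``n_arcs`` arcs."""
    rng = random.Random(seed)
    names = _names(n)
    cands = [(u, v) for u in names for v in names if u != v]
    rng.shuffle(cands)
    return Digraph(set(names), set(cands[:n_arcs]))


def maxdicut_to_star(digraph: Digraph) -> GraphInstance:
    """Star instance whose orientation optimum equals the maximum dicut.

    A fresh center r is attached to every digraph vertex and each arc
    becomes a source-target pair; orienting leaf edges toward/away from
    the center encodes the cut side of each vertex.
    """
    if not digraph.vertices:
        raise ValueError("digraph must be nonempty")
    center = "r"
    while center in digraph.vertices:
        center += "_"
    vertices = set(digraph.vertices) | {center}
    edges = {edge_key(v, center) for v in digraph.vertices}
    pairs = [SourceTargetPair(u, v, 1.0) for u, v in sorted(digraph.arcs)]
    return GraphInstance(vertices, edges, pairs)


def max_dicut_brute(digraph: Digraph) -> int:
    """Maximum number of arcs leaving a vertex subset, by enumeration."""
    verts = sorted(digraph.vertices)
    best = 0
    for bits in product((0, 1), repeat=len(verts)):
        inside = {v for v, b in zip(verts, bits) if b}
        cut = sum(1 for u, v in digraph.arcs if u in inside and v not in inside)
        best = max(best, cut)
    return best
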