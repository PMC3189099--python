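"""Core domain types for tree-orientation instances.

An instance consists of an undirected network and a list of ordered
source-target pairs ("signals", e.g. cause-effect pairs from knockout
experiments).  An *orientation* assigns a direction to every edge; a pair
[s, t] is *satisfied* when the oriented graph contains a directed path from
s to t.  The optimization goal is to maximize the total weight of satisfied
pairs.

Vertices are opaque strings.  Undirected edges are canonically stored as
sorted 2-tuples; :func:`edge_key` produces the canonical form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Edge",
    "edge_key",
    "SourceTargetPair",
    "GraphInstance",
    "TreeInstance",
    "MTOInstance",
    "Orientation",
    "SolveResult",
    "InstanceError",
    "ParseError",
    "read_instance",
    "tree_path",
    "score_orientation",
    "write_orientation",
    "read_orientation",
]

Edge = tuple[str, str]

#: absolute tolerance for weight comparisons throughout the package
WEIGHT_ATOL = 1e-9


class InstanceError(ValueError):
    """Raised when an instance violates a structural invariant."""


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


def edge_key(u: str, v: str) -> Edge:
    """Canonical (sorted) representation of the undirected edge {u, v}."""
    if u == v:
        raise InstanceError(f"self-loop edge on vertex {u!r}")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class SourceTargetPair:
    """An ordered signal pair [source, target] with a nonnegative weight."""

    source: str
    target: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise InstanceError(
                f"pair [{self.source}, {self.target}] has negative weight {self.weight}"
            )


@dataclass
class GraphInstance:
    """An undirected network plus weighted ordered pairs, pre-contraction.

    The graph need not be connected or acyclic.  ``self_pair_weight`` records
    the total weight of pairs with source = target that were dropped during
    normalization (such pairs are satisfied by every orientation).
    """

    vertices: set[str]
    edges: set[Edge]
    pairs: list[SourceTargetPair]
    self_pair_weight: float = 0.0

    def validate(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise InstanceError(f"self-loop edge on vertex {u!r}")
            if u not in self.vertices or v not in self.vertices:
                raise InstanceError(f"edge ({u}, {v}) has endpoint outside vertex set")
        for p in self.pairs:
            for endpoint in (p.source, p.target):
                if endpoint not in self.vertices:
                    raise InstanceError(f"pair endpoint {endpoint!r} is not a vertex")

    def total_pair_weight(self) -> float:
        return sum(p.weight for p in self.pairs)


class TreeInstance:
    """A connected acyclic graph with an adjacency index."""

    def __init__(self, vertices: Iterable[str], edges: Iterable[Edge]):
        self.vertices: set[str] = set(vertices)
        self.edges: set[Edge] = {edge_key(u, v) for u, v in edges}
        self.adj: dict[str, list[str]] = {v: [] for v in self.vertices}
        for u, v in self.edges:
            self.adj[u].append(v)
            self.adj[v].append(u)
        for v in self.adj:
            self.adj[v].sort()
        self._check_tree()

    def _check_tree(self) -> None:
        n = len(self.vertices)
        if n == 0:
            raise InstanceError("empty tree")
        if len(self.edges) != n - 1:
            raise InstanceError(
                f"tree must have |V|-1 edges, got {len(self.edges)} for {n} vertices"
            )
        # connectivity by BFS from an arbitrary vertex
        start = next(iter(self.vertices))
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if len(seen) != n:
            raise InstanceError("tree is not connected")


@dataclass
class MTOInstance:
    """A tree together with weighted ordered pairs: the object all solvers consume."""

    tree: TreeInstance
    pairs: list[SourceTargetPair]

    def __post_init__(self) -> None:
        for p in self.pairs:
            for endpoint in (p.source, p.target):
                if endpoint not in self.tree.vertices:
                    raise InstanceError(f"pair endpoint {endpoint!r} is not a tree vertex")

    def total_pair_weight(self) -> float:
        return sum(p.weight for p in self.pairs)


class Orientation:
    """One direction per tree edge: a map from canonical edge to (tail, head)."""

    def __init__(self, arcs: Mapping[Edge, tuple[str, str]] | Iterable[tuple[str, str]] = ()):
        self.arcs: dict[Edge, tuple[str, str]] = {}
        if isinstance(arcs, Mapping):
            items = arcs.values()
        else:
            items = arcs
        for tail, head in items:
            self.add_arc(tail, head)

    def add_arc(self, tail: str, head: str) -> None:
        key = edge_key(tail, head)
        existing = self.arcs.get(key)
        if existing is not None and existing != (tail, head):
            raise InstanceError(f"conflicting directions for edge {key}")
        self.arcs[key] = (tail, head)

    def direction(self, u: str, v: str) -> tuple[str, str]:
        """The arc chosen for the undirected edge {u, v}."""
        key = edge_key(u, v)
        try:
            return self.arcs[key]
        except KeyError:
            raise InstanceError(f"orientation is missing edge {key}") from None

    def has_arc(self, tail: str, head: str) -> bool:
        return self.arcs.get(edge_key(tail, head)) == (tail, head)

    def __len__(self) -> int:
        return len(self.arcs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Orientation) and self.arcs == other.arcs

    def sorted_arcs(self) -> list[tuple[str, str]]:
        return sorted(self.arcs.values())


@dataclass
class SolveResult:
    """Optimal value plus a witness.

    ``unsatisfied_count`` is the parameter k of the decision problem: the
    number of pairs not satisfied by the witness orientation.
    """

    satisfied_weight: float
    unsatisfied_weight: float
    satisfied_pairs: set[int]
    unsatisfied_count: int
    orientation: Orientation
    algorithm: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "satisfied_weight": self.satisfied_weight,
                "unsatisfied_weight": self.unsatisfied_weight,
                "k": self.unsatisfied_count,
                "satisfied_pairs": sorted(self.satisfied_pairs),
                "algorithm": self.algorithm,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# file I/O

def _parse_tsv(path: str) -> Iterable[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_instance(edges_path: str, pairs_path: str) -> GraphInstance:
    """Parse an edge-list TSV and a pair-list TSV into a GraphInstance.

    Edge lines are ``u<TAB>v``; pair lines ``s<TAB>t[<TAB>weight]`` with unit
    weight when the column is absent.  Duplicate pairs are merged by summing
    their weights; pairs with source = target are dropped and their weight
    accumulated in ``self_pair_weight`` (they are satisfied by any
    orientation).
    """
    vertices: set[str] = set()
    edges: set[Edge] = set()
    for lineno, fields in _parse_tsv(edges_path):
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{edges_path}:{lineno}: expected 'u<TAB>v', got {fields!r}")
        u, v = fields
        if u == v:
            raise ParseError(f"{edges_path}:{lineno}: self-loop edge on {u!r}")
        vertices.update((u, v))
        edges.add(edge_key(u, v))

    merged: dict[tuple[str, str], float] = {}
    self_weight = 0.0
    for lineno, fields in _parse_tsv(pairs_path):
        if len(fields) not in (2, 3) or not fields[0] or not fields[1]:
            raise ParseError(
                f"{pairs_path}:{lineno}: expected 's<TAB>t[<TAB>weight]', got {fields!r}"
            )
        s, t = fields[0], fields[1]
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError:
                raise ParseError(f"{pairs_path}:{lineno}: bad weight {fields[2]!r}") from None
        else:
            w = 1.0
        if w < 0:
            raise ParseError(f"{pairs_path}:{lineno}: negative weight {w}")
        if s not in vertices or t not in vertices:
            missing = s if s not in vertices else t
            raise ParseError(f"{pairs_path}:{lineno}: pair endpoint {missing!r} is not a vertex")
        if s == t:
            self_weight += w
            continue
        merged[(s, t)] = merged.get((s, t), 0.0) + w

    pairs = [SourceTargetPair(s, t, w) for (s, t), w in sorted(merged.items())]
    inst = GraphInstance(vertices, edges, pairs, self_pair_weight=self_weight)
    inst.validate()
    return inst


def normalize_pairs(pairs: Iterable[SourceTargetPair]) -> tuple[list[SourceTargetPair], float]:
    """Merge duplicate pairs and drop s = t pairs; return (pairs, dropped weight)."""
    merged: dict[tuple[str, str], float] = {}
    self_weight = 0.0
    for p in pairs:
        if p.source == p.target:
            self_weight += p.weight
            continue
        merged[(p.source, p.target)] = merged.get((p.source, p.target), 0.0) + p.weight
    out = [SourceTargetPair(s, t, w) for (s, t), w in sorted(merged.items())]
    return out, self_weight


def tree_path(rooted, s: str, t: str) -> list[str]:
    """The unique simple path from s to t, via their least common ancestor.

    ``rooted`` is a :class:`~treeorient.rooted.RootedTree`.  Returns the path
    in order from s to t; ``tree_path(r, v, v) == [v]``.
    """
    anc = rooted.lca(s, t)
    up = []
    x = s
    while x != anc:
        up.append(x)
        x = rooted.parent[x]
    down = []
    x = t
    while x != anc:
        down.append(x)
        x = rooted.parent[x]
    return up + [anc] + list(reversed(down))


def path_arcs(path: Sequence[str]) -> list[tuple[str, str]]:
    """Consecutive (tail, head) arcs along a vertex sequence."""
    return [(path[i], path[i + 1]) for i in range(len(path) - 1)]


def score_orientation(
    instance: MTOInstance, orientation: Orientation, rooted=None
) -> tuple[float, set[int]]:
    """Total weight and index set of pairs satisfied by ``orientation``.

    A pair is satisfied iff every edge on its tree path is oriented in the
    path direction.  Raises if the orientation misses a tree edge.
    """
    from .rooted import build_rooted  # local import to avoid a cycle

    for e in instance.tree.edges:
        if e not in orientation.arcs:
            raise InstanceError(f"orientation is missing tree edge {e}")
    if rooted is None:
        rooted = build_rooted(instance.tree, min(instance.tree.vertices))
    satisfied: set[int] = set()
    weight = 0.0
    for idx, p in enumerate(instance.pairs):
        path = tree_path(rooted, p.source, p.target)
        if all(orientation.has_arc(a, b) for a, b in path_arcs(path)):
            satisfied.add(idx)
            weight += p.weight
    return weight, satisfied


def write_orientation(orientation: Orientation, path: str) -> None:
    """Write one ``tail<TAB>head`` line per arc, sorted by (tail, head)."""
    with open(path, "w", encoding="utf-8") as fh:
        for tail, head in orientation.sorted_arcs():
            fh.write(f"{tail}\t{head}\n")


def read_orientation(path: str) -> Orientation:
    orient = Orientation()
    for lineno, fields in _parse_tsv(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'tail<TAB>head', got {fields!r}")
        orient.add_arc(fields[0], fields[1])
    return orient
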