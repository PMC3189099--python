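"""Tree dynamic programs for weighted maximum tree orientation.

Two solvers are provided for a rooted instance (T, P, w):

* :func:`solve_crossfree` — quadratic-time DP for *cross-pair-free*
  instances, i.e. rootings under which every pair has one endpoint an
  ancestor of the other.  The table entry S(v, w) (for an ancestor v of w)
  is the best weight achievable on the subtree hanging from w plus the
  v..w path, given that the path is oriented from v to w; S(w, v) fixes
  the opposite path direction.  The optimum is S(r, r).

* :func:`solve_crosspairs` — fixed-parameter DP in the number of cross
  pairs through a vertex.  Each table slice at a vertex w is indexed by a
  0/1 coloring of the cross pairs through w (1 = "must be satisfiable");
  infeasible colorings get value -inf, and parent and child colorings must
  agree on shared cross pairs.  Satisfied cross pairs are credited at
  their lowest common ancestor.

Both solvers share the helper table A(v, w): the total weight of pairs
with both endpoints on the v..w path that are satisfied when the path is
oriented from v to w.  A is filled in quadratic time by extending paths
one edge at a time in breadth order.

Each solver reconstructs a witness orientation from recorded argmax
choices and re-scores it; the reported optimum is the re-scored value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, isinf

from .conflict import pairs_conflict
from .model import (
    MTOInstance,
    Orientation,
    SolveResult,
    edge_key,
    path_arcs,
    score_orientation,
    tree_path,
)
from .rooted import RootedTree, build_rooted

__all__ = [
    "ATable",
    "CrossPairIndex",
    "compute_A",
    "compute_A_direct",
    "find_crossfree_root",
    "cross_pair_index",
    "choose_root_min_qv",
    "solve_crossfree",
    "solve_crosspairs",
    "QV_CAP",
]

#: hard cap on the per-vertex cross-pair count (table size is 2^q_v)
QV_CAP = 22

_TIE_EPS = 1e-12


class CrossPairError(ValueError):
    """A cross pair was found where a cross-pair-free rooting was required."""


@dataclass
class ATable:
    """A(v, w) for ordered ancestor/descendant-or-equal vertex pairs."""

    values: dict[tuple[str, str], float]

    def __call__(self, v: str, w: str) -> float:
        if v == w:
            return 0.0
        return self.values[(v, w)]


@dataclass
class CrossPairIndex:
    """Cross pairs of a rooted instance.

    ``Q`` holds the indices of pairs [s, t] for which neither endpoint is
    an ancestor of the other; ``Q_v`` maps each vertex to the cross pairs
    whose path passes through it (endpoints included); ``q_v_of_root`` is
    max_v |Q_v|, the parameter governing the coloring DP.
    """

    Q: set[int]
    Q_v: dict[str, list[int]]
    q_v_of_root: int


def _ancestor_chain(rooted: RootedTree, w: str) -> list[str]:
    """[w, parent(w), ..., root]."""
    chain = [w]
    while rooted.parent[chain[-1]] is not None:
        chain.append(rooted.parent[chain[-1]])
    return chain


def _pair_weight_map(instance: MTOInstance) -> dict[tuple[str, str], float]:
    wmap: dict[tuple[str, str], float] = {}
    for p in instance.pairs:
        wmap[(p.source, p.target)] = wmap.get((p.source, p.target), 0.0) + p.weight
    return wmap


def compute_A(instance: MTOInstance, rooted: RootedTree) -> ATable:
    """Path-weight table by single-edge extension.

    For v strictly above w with neighbors x (of v) and y (of w) on the
    v..w path, A(v, w) = w([v, w]) + A(v, y) + A(x, w) - A(x, y): the new
    endpoints contribute only the pair [v, w] beyond the two overlapping
    sub-paths.  Vertices are processed root-down so shorter paths are
    always available first.
    """
    wmap = _pair_weight_map(instance)
    A: dict[tuple[str, str], float] = {}

    def a(p: str, q: str) -> float:
        return 0.0 if p == q else A[(p, q)]

    for w in rooted.order:  # preorder: parents before children
        chain = _ancestor_chain(rooted, w)
        for i in range(1, len(chain)):
            v = chain[i]
            if i == 1:
                A[(v, w)] = wmap.get((v, w), 0.0)
                A[(w, v)] = wmap.get((w, v), 0.0)
            else:
                x = chain[i - 1]  # neighbor of v towards w
                y = chain[1]      # neighbor of w towards v (= parent of w)
                A[(v, w)] = wmap.get((v, w), 0.0) + a(v, y) + a(x, w) - a(x, y)
                A[(w, v)] = wmap.get((w, v), 0.0) + a(w, x) + a(y, v) - a(y, x)
    return ATable(A)


def compute_A_direct(instance: MTOInstance, rooted: RootedTree) -> ATable:
    """Reference construction of A by explicit summation over path pairs."""
    A: dict[tuple[str, str], float] = {}
    for w in rooted.order:
        chain = _ancestor_chain(rooted, w)
        for i in range(1, len(chain)):
            v = chain[i]
            on_path = set(chain[: i + 1])
            down = up = 0.0
            for p in instance.pairs:
                if p.source in on_path and p.target in on_path:
                    if rooted.is_ancestor(p.source, p.target):
                        down += p.weight
                    else:
                        up += p.weight
            A[(v, w)] = down
            A[(w, v)] = up
    return ATable(A)


# ---------------------------------------------------------------------------
# cross pairs

def cross_pair_index(instance: MTOInstance, rooted: RootedTree) -> CrossPairIndex:
    Q: set[int] = set()
    Q_v: dict[str, list[int]] = {v: [] for v in rooted.order}
    for idx, p in enumerate(instance.pairs):
        anc = rooted.lca(p.source, p.target)
        if anc != p.source and anc != p.target:
            Q.add(idx)
            for v in tree_path(rooted, p.source, p.target):
                Q_v[v].append(idx)
    qv = max((len(lst) for lst in Q_v.values()), default=0)
    for lst in Q_v.values():
        lst.sort()
    return CrossPairIndex(Q=Q, Q_v=Q_v, q_v_of_root=qv)


def find_crossfree_root(instance: MTOInstance) -> str | None:
    """A root under which no pair is a cross pair, or None.

    Tries every vertex in lexicographic order; for instances with no pairs
    this returns the smallest vertex.
    """
    for root in sorted(instance.tree.vertices):
        rooted = build_rooted(instance.tree, root)
        if all(
            rooted.lca(p.source, p.target) in (p.source, p.target)
            for p in instance.pairs
        ):
            return root
    return None


def choose_root_min_qv(instance: MTOInstance) -> tuple[str, int]:
    """The root minimizing the maximum number of cross pairs per vertex."""
    best_root: str | None = None
    best_qv = -1
    for root in sorted(instance.tree.vertices):
        rooted = build_rooted(instance.tree, root)
        qv = cross_pair_index(instance, rooted).q_v_of_root
        if best_root is None or qv < best_qv:
            best_root, best_qv = root, qv
    assert best_root is not None
    return best_root, best_qv


# ---------------------------------------------------------------------------
# cross-pair-free DP

def solve_crossfree(instance: MTOInstance, rooted: RootedTree) -> SolveResult:
    """Quadratic DP for a cross-pair-free rooting; raises on a cross pair."""
    cpi = cross_pair_index(instance, rooted)
    if cpi.Q:
        bad = instance.pairs[min(cpi.Q)]
        raise CrossPairError(
            f"pair [{bad.source}, {bad.target}] is a cross pair under root "
            f"{rooted.root!r}; use the coloring solver"
        )
    A = compute_A(instance, rooted)
    S: dict[tuple[str, str], float] = {}
    # per entry, per child of the lower vertex: the follow-up entry key
    choice: dict[tuple[str, str], list[tuple[str, str]]] = {}

    for w in rooted.postorder():
        kids = rooted.children[w]
        chain = _ancestor_chain(rooted, w)
        for v in chain[1:]:
            for entry, alt_a, alt_b in (
                ((v, w), lambda u: (u, w), lambda u: (v, u)),
                ((w, v), lambda u: (w, u), lambda u: (u, v)),
            ):
                base = A(*entry)
                total = base
                picks: list[tuple[str, str]] = []
                for u in kids:
                    ka, kb = alt_a(u), alt_b(u)
                    va = S[ka]
                    vb = S[kb] - base
                    if va >= vb - _TIE_EPS:
                        total += va
                        picks.append(ka)
                    else:
                        total += vb
                        picks.append(kb)
                S[entry] = total
                choice[entry] = picks
        # diagonal entry: best orientation of the subtree rooted at w
        total = 0.0
        picks = []
        for u in kids:
            va, vb = S[(u, w)], S[(w, u)]
            if va >= vb - _TIE_EPS:
                total += va
                picks.append((u, w))
            else:
                total += vb
                picks.append((w, u))
        S[(w, w)] = total
        choice[(w, w)] = picks

    r = rooted.root
    orient = Orientation()
    stack: list[tuple[str, str]] = [(r, r)]
    while stack:
        a, b = stack.pop()
        if a != b:
            for t, h in path_arcs(tree_path(rooted, a, b)):
                orient.add_arc(t, h)
        stack.extend(choice[(a, b)])

    weight, satisfied = score_orientation(instance, orient, rooted)
    assert abs(weight - S[(r, r)]) < 1e-6, "witness re-score disagrees with DP value"
    total_w = instance.total_pair_weight()
    return SolveResult(
        satisfied_weight=weight,
        unsatisfied_weight=total_w - weight,
        satisfied_pairs=satisfied,
        unsatisfied_count=len(instance.pairs) - len(satisfied),
        orientation=orient,
        algorithm="crossfree",
    )


# ---------------------------------------------------------------------------
# cross-pair coloring DP

def _masks(indices: list[int]):
    """All colorings of ``indices`` as frozensets of 1-colored pair indices,
    in lexicographic order of the bit tuples (ascending pair index = most
    significant bit last is irrelevant for correctness; the order is fixed
    for determinism)."""
    out = []
    k = len(indices)
    for mask in range(1 << k):
        out.append(frozenset(indices[i] for i in range(k) if mask >> i & 1))
    return out


def solve_crosspairs(
    instance: MTOInstance, rooted: RootedTree, qv_cap: int = QV_CAP
) -> SolveResult:
    """Coloring DP over cross pairs; exact for any rooted instance.

    Runs in O(2^q_v(r) * q_v(r) * n^2)-ish time where q_v(r) is the
    maximum number of cross pairs through a vertex under this rooting;
    refuses instances with q_v(r) > ``qv_cap``.
    """
    cpi = cross_pair_index(instance, rooted)
    if cpi.q_v_of_root > qv_cap:
        raise ValueError(
            f"q_v(root) = {cpi.q_v_of_root} exceeds the cap {qv_cap}; "
            "the coloring table would need 2^q_v entries per vertex"
        )
    A = compute_A(instance, rooted)
    pairs = instance.pairs

    # directed edges and LCA of every cross pair's path
    dirs: dict[int, dict] = {}
    lca_of: dict[int, str] = {}
    for q in cpi.Q:
        p = pairs[q]
        dirs[q] = {
            edge_key(a, b): (a, b)
            for a, b in path_arcs(tree_path(rooted, p.source, p.target))
        }
        lca_of[q] = rooted.lca(p.source, p.target)

    cross_conflicts: dict[int, set[int]] = {q: set() for q in cpi.Q}
    qlist = sorted(cpi.Q)
    for i, qi in enumerate(qlist):
        for qj in qlist[i + 1:]:
            if pairs_conflict(rooted, pairs[qi], pairs[qj]):
                cross_conflicts[qi].add(qj)
                cross_conflicts[qj].add(qi)

    def locally_feasible(ones: frozenset) -> bool:
        return all(cross_conflicts[q].isdisjoint(ones) for q in ones)

    def feasible_on_path(ones: frozenset, arcs: list[tuple[str, str]]) -> bool:
        """Can every 1-colored cross pair coexist with the given path arcs?"""
        for a, b in arcs:
            e = edge_key(a, b)
            for q in ones:
                want = dirs[q].get(e)
                if want is not None and want != (a, b):
                    return False
        return True

    def w_lca(w: str, ones: frozenset) -> float:
        return sum(pairs[q].weight for q in ones if lca_of[q] == w)

    colorings: dict[str, list[frozenset]] = {
        w: _masks(cpi.Q_v[w]) for w in rooted.order
    }
    # agreement groups: per (parent w, child u), child colorings bucketed by
    # their restriction to the shared cross pairs
    groups: dict[tuple[str, str], dict[frozenset, list[frozenset]]] = {}
    for w in rooted.order:
        shared_base = set(cpi.Q_v[w])
        for u in rooted.children[w]:
            shared = frozenset(shared_base & set(cpi.Q_v[u]))
            bucket: dict[frozenset, list[frozenset]] = {}
            for cu in colorings[u]:
                bucket.setdefault(cu & shared, []).append(cu)
            groups[(w, u)] = bucket

    shared_key = {
        (w, u): frozenset(set(cpi.Q_v[w]) & set(cpi.Q_v[u]))
        for w in rooted.order
        for u in rooted.children[w]
    }

    S: dict[tuple[str, str], dict[frozenset, float]] = {}
    choice: dict[tuple[str, str, frozenset], list[tuple[tuple[str, str], frozenset]]] = {}

    def best_child(
        w: str, u: str, ones: frozenset, cands: list[tuple[tuple[str, str], float]]
    ) -> tuple[float, tuple[tuple[str, str], frozenset] | None]:
        """Maximize over child colorings agreeing with ``ones`` and over the
        two orientation branches given as (entry, offset) candidates."""
        bucket = groups[(w, u)]
        key = ones & shared_key[(w, u)]
        best = -inf
        pick = None
        for entry, offset in cands:
            table = S[entry]
            for cu in bucket.get(key, ()):
                val = table[cu] + offset
                if val > best + _TIE_EPS:
                    best = val
                    pick = (entry, cu)
        return best, pick

    for w in rooted.postorder():
        kids = rooted.children[w]
        chain = _ancestor_chain(rooted, w)
        # path arcs for each ancestor v (chain[i], i >= 1): chain bottom-up
        for i in range(len(chain)):
            v = chain[i]
            if i == 0:
                entries = [((w, w), 0.0, None)]
            else:
                down_arcs = [(chain[j + 1], chain[j]) for j in range(i)]
                up_arcs = [(chain[j], chain[j + 1]) for j in range(i)]
                entries = [
                    ((v, w), A(v, w), down_arcs),
                    ((w, v), A(w, v), up_arcs),
                ]
            for entry, base, arcs in entries:
                table: dict[frozenset, float] = {}
                for ones in colorings[w]:
                    if not locally_feasible(ones) or (
                        arcs is not None and not feasible_on_path(ones, arcs)
                    ):
                        table[ones] = -inf
                        continue
                    total = base + w_lca(w, ones)
                    picks: list[tuple[tuple[str, str], frozenset]] = []
                    for u in kids:
                        if entry == (w, w):
                            cands = [((w, u), 0.0), ((u, w), 0.0)]
                        elif entry == (v, w):
                            cands = [((v, u), -base), ((u, w), 0.0)]
                        else:  # (w, v): path oriented upward
                            cands = [((u, v), -base), ((w, u), 0.0)]
                        m, pick = best_child(w, u, ones, cands)
                        if isinf(m) and m < 0:
                            total = -inf
                            break
                        total += m
                        picks.append(pick)  # type: ignore[arg-type]
                    table[ones] = total
                    if not isinf(total):
                        choice[(entry[0], entry[1], ones)] = picks
                S[entry] = table

    r = rooted.root
    best = -inf
    best_ones: frozenset | None = None
    for ones in colorings[r]:
        val = S[(r, r)][ones]
        if val > best + _TIE_EPS:
            best = val
            best_ones = ones
    assert best_ones is not None and not isinf(best)

    orient = Orientation()
    stack: list[tuple[str, str, frozenset]] = [(r, r, best_ones)]
    while stack:
        a, b, ones = stack.pop()
        if a != b:
            for t, h in path_arcs(tree_path(rooted, a, b)):
                orient.add_arc(t, h)
        for (entry, cu) in choice.get((a, b, ones), ()):
            stack.append((entry[0], entry[1], cu))

    # vertices never reached by any entry cannot exist, but leaves with no
    # pairs may leave their pendant edge unset only if choice lists were
    # empty; every child always receives an entry, so the orientation is
    # complete.
    weight, satisfied = score_orientation(instance, orient, rooted)
    assert abs(weight - best) < 1e-6, "witness re-score disagrees with DP value"
    total_w = instance.total_pair_weight()
    return SolveResult(
        satisfied_weight=weight,
        unsatisfied_weight=total_w - weight,
        satisfied_pairs=satisfied,
        unsatisfied_count=len(instance.pairs) - len(satisfied),
        orientation=orient,
        algorithm="crosspairs",
    )
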