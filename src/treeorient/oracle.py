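"""Brute-force reference solver: enumerate every orientation of the tree.

This is the correctness anchor for all other solvers and is deliberately
kept free of pruning.  Edges are enumerated in lexicographic order with
direction bit 0 meaning low-endpoint -> high-endpoint, and the first
optimum encountered is returned, so the witness is the lexicographically
smallest optimal orientation under that encoding.
"""

from __future__ import annotations

from itertools import product

from .model import MTOInstance, Orientation, SolveResult, edge_key, path_arcs, tree_path
from .rooted import build_rooted

__all__ = ["brute_force_solve", "MAX_BRUTE_EDGES"]

MAX_BRUTE_EDGES = 20


def brute_force_solve(instance: MTOInstance) -> SolveResult:
    """Exact optimum by enumerating all 2^|E| orientations (|E| <= 20)."""
    edges = sorted(instance.tree.edges)
    if len(edges) > MAX_BRUTE_EDGES:
        raise ValueError(
            f"brute force is capped at {MAX_BRUTE_EDGES} edges "
            f"(got {len(edges)}); use a dynamic-programming or vertex-cover solver"
        )
    rooted = build_rooted(instance.tree, min(instance.tree.vertices))
    # pre-resolve each pair's path to (edge position, forward?) tests
    edge_pos = {e: i for i, e in enumerate(edges)}
    pair_tests: list[tuple[float, list[tuple[int, bool]]]] = []
    for p in instance.pairs:
        tests = []
        for a, b in path_arcs(tree_path(rooted, p.source, p.target)):
            e = edge_key(a, b)
            tests.append((edge_pos[e], (a, b) == e))  # True: traversed low->high
        pair_tests.append((p.weight, tests))

    best_weight = -1.0
    best_bits: tuple[int, ...] | None = None
    best_sat: set[int] = set()
    for bits in product((0, 1), repeat=len(edges)):
        weight = 0.0
        sat = set()
        for idx, (w, tests) in enumerate(pair_tests):
            # bit 0 orients the edge low->high
            if all((bits[pos] == 0) == forward for pos, forward in tests):
                weight += w
                sat.add(idx)
        if weight > best_weight + 1e-12:
            best_weight = weight
            best_bits = bits
            best_sat = sat

    assert best_bits is not None
    orient = Orientation()
    for bit, (u, v) in zip(best_bits, edges):
        if bit == 0:
            orient.add_arc(u, v)
        else:
            orient.add_arc(v, u)
    total = instance.total_pair_weight()
    return SolveResult(
        satisfied_weight=best_weight,
        unsatisfied_weight=total - best_weight,
        satisfied_pairs=best_sat,
        unsatisfied_count=len(instance.pairs) - len(best_sat),
        orientation=orient,
        algorithm="brute",
    )
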