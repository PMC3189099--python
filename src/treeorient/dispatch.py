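"""Solver portfolio: pick an exact algorithm from instance parameters.

``solve_tree`` solves a tree instance with a named algorithm or with
``auto`` selection; ``solve_dispatch`` handles an arbitrary connected
network: contract bridge blocks, solve the tree, lift the orientation
back, and account for the pairs satisfied for free inside blocks.

Auto order: a cross-pair-free rooting exists -> quadratic DP; else
m_e <= 2 -> elimination pipeline; else q_v small -> coloring DP; else
m_v small -> vertex cover on the P_v decomposition; else branch and
bound.  The thresholds bound table sizes (2^q_v colorings, 2^m_v bag
subsets) and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .conflict import build_conflict_graph
from .dp import (
    choose_root_min_qv,
    cross_pair_index,
    find_crossfree_root,
    solve_crossfree,
    solve_crosspairs,
)
from .model import GraphInstance, MTOInstance, Orientation, SolveResult, tree_path
from .oracle import brute_force_solve
from .preprocess import BlockMapping, contract_to_tree, lift_orientation
from .rooted import build_rooted
from .vc import branch_vertex_cover, mv_decomposition, result_from_cover, solve_me2, treedec_vertex_cover

__all__ = ["ALGORITHMS", "DispatchResult", "solve_tree", "solve_dispatch"]

ALGORITHMS = ("auto", "brute", "crossfree", "crosspairs", "vc-branch", "vc-treedec", "me2")

QV_DISPATCH = 16
MV_DISPATCH = 20


def _mv(instance: MTOInstance, rooted) -> int:
    counts = {v: 0 for v in instance.tree.vertices}
    for p in instance.pairs:
        for v in tree_path(rooted, p.source, p.target):
            counts[v] += 1
    return max(counts.values(), default=0)


def solve_tree(
    instance: MTOInstance,
    algorithm: str = "auto",
    root: str | None = None,
    qv_threshold: int = QV_DISPATCH,
    mv_threshold: int = MV_DISPATCH,
) -> SolveResult:
    """Solve a tree instance exactly with the requested algorithm."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")

    if algorithm == "auto":
        cf_root = find_crossfree_root(instance) if root is None else root
        if root is None and cf_root is not None:
            return solve_tree(instance, "crossfree", cf_root)
        base = build_rooted(instance.tree, root or min(instance.tree.vertices))
        _cg, load = build_conflict_graph(instance, base)
        if load.m_e <= 2:
            return solve_tree(instance, "me2", root)
        qv_root, qv = choose_root_min_qv(instance) if root is None else (
            root,
            cross_pair_index(instance, build_rooted(instance.tree, root)).q_v_of_root,
        )
        if qv <= qv_threshold:
            return solve_tree(instance, "crosspairs", qv_root)
        if _mv(instance, base) <= mv_threshold:
            return solve_tree(instance, "vc-treedec", root)
        return solve_tree(instance, "vc-branch", root)

    if algorithm == "brute":
        return brute_force_solve(instance)

    if algorithm == "crossfree":
        if root is None:
            root = find_crossfree_root(instance)
            if root is None:
                raise ValueError(
                    "no cross-pair-free rooting exists; use crosspairs or a "
                    "vertex-cover algorithm"
                )
        return solve_crossfree(instance, build_rooted(instance.tree, root))

    if algorithm == "crosspairs":
        if root is None:
            root, _ = choose_root_min_qv(instance)
        return solve_crosspairs(instance, build_rooted(instance.tree, root))

    rooted = build_rooted(instance.tree, root or min(instance.tree.vertices))

    if algorithm == "me2":
        return solve_me2(instance, rooted)

    cg, _load = build_conflict_graph(instance, rooted)
    if algorithm == "vc-branch":
        cover, weight = branch_vertex_cover(cg)
        return result_from_cover(instance, rooted, cover, weight, "vc-branch")

    # vc-treedec
    td = mv_decomposition(instance, rooted, cg)
    if td.width + 1 > mv_threshold:
        raise ValueError(
            f"m_v = {td.width + 1} exceeds the bag-subset threshold {mv_threshold}"
        )
    cover, weight = treedec_vertex_cover(cg, td)
    return result_from_cover(instance, rooted, cover, weight, "vc-treedec")


@dataclass
class DispatchResult:
    """Full-network solve: tree result plus contraction accounting.

    ``satisfied_weight`` includes the weight of pairs satisfied for free
    (both endpoints in one contracted block, plus source = target pairs);
    ``satisfied_pairs`` indexes the normalized original pair list.
    """

    tree_result: SolveResult
    mapping: BlockMapping
    orientation: Orientation          # over the original graph edges
    auto_satisfied_weight: float
    satisfied_weight: float
    unsatisfied_weight: float
    satisfied_pairs: set[int]
    unsatisfied_count: int
    algorithm: str
    log: dict = field(default_factory=dict)


def solve_dispatch(
    graph: GraphInstance, algorithm: str = "auto", root: str | None = None
) -> DispatchResult:
    """Contract, solve the tree instance, and lift the orientation back."""
    mto, mapping, auto_weight = contract_to_tree(graph)
    result = solve_tree(mto, algorithm=algorithm, root=root)
    lifted = lift_orientation(graph, mapping, result.orientation)

    satisfied_orig: set[int] = set(mapping.auto_satisfied_pairs)
    for idx in result.satisfied_pairs:
        satisfied_orig.update(mapping.pair_origin[idx])
    n_norm = len(mapping.auto_satisfied_pairs) + sum(
        len(v) for v in mapping.pair_origin.values()
    )
    total_sat = result.satisfied_weight + auto_weight + graph.self_pair_weight
    total_w = (
        sum(p.weight for p in mto.pairs) + auto_weight + graph.self_pair_weight
    )
    return DispatchResult(
        tree_result=result,
        mapping=mapping,
        orientation=lifted,
        auto_satisfied_weight=auto_weight,
        satisfied_weight=total_sat,
        unsatisfied_weight=total_w - total_sat,
        satisfied_pairs=satisfied_orig,
        unsatisfied_count=n_norm - len(satisfied_orig),
        algorithm=result.algorithm,
        log={
            "n_t": len(mto.tree.vertices),
            "p_t": len(mto.pairs),
            "auto_satisfied_weight": auto_weight,
            "algorithm": result.algorithm,
        },
    )
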