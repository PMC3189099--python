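"""Structural parameter panel of an orientation instance.

The panel collects the quantities that govern which exact solver is
practical: instance sizes before and after bridge-block contraction, the
maximum signal flow per vertex (m_v) and per edge (m_e), cross-pair counts
before (q, q_v) and after (q', q_v') dropping pairs that conflict with
nothing, conflict-graph size (n_c, m_c), and optionally the optimum number
of unsatisfiable pairs k.

Cross-pair counts are rooting-dependent; the panel reports them under the
root that minimizes the maximum number of cross pairs per vertex, the one
canonical rooting the theory singles out.  n_c counts only pairs that
conflict with at least one other pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conflict import build_conflict_graph, reduce_conflict_graph
from .model import GraphInstance, MTOInstance, tree_path
from .preprocess import contract_to_tree
from .rooted import build_rooted
from .dp import choose_root_min_qv, cross_pair_index

__all__ = ["ParameterPanel", "parameter_panel"]


@dataclass
class ParameterPanel:
    n: int            # network vertices
    m: int            # network edges
    p: int            # pairs (after normalization)
    n_t: int          # tree vertices after contraction
    p_t: int          # pairs after contraction
    n_star: int       # 1 + maximum tree degree ("vertices in star")
    m_v: int          # max pair paths through a tree vertex
    m_e: int          # max pair paths through a tree edge
    q: int            # cross pairs (under the q_v-minimizing root)
    q_v: int          # max cross pairs per vertex, minimized over roots
    q_prime: int      # cross pairs after dropping conflict-free pairs
    q_v_prime: int    # q_v after dropping conflict-free pairs
    n_c: int          # conflict-graph nodes with at least one conflict
    m_c: int          # conflict-graph edges
    k: int | None     # minimum number of unsatisfiable pairs (if computed)

    def check_invariants(self) -> None:
        assert self.q_v <= self.q
        assert self.q_v_prime <= self.q_prime <= self.q
        assert self.m_e <= self.m_v
        if self.k is not None:
            assert self.k <= self.p_t
        for name, value in vars(self).items():
            if value is not None:
                assert value >= 0, f"{name} negative"

    def to_dict(self) -> dict:
        return dict(vars(self))


def _mv(instance: MTOInstance, rooted) -> int:
    counts = {v: 0 for v in instance.tree.vertices}
    for p in instance.pairs:
        for v in tree_path(rooted, p.source, p.target):
            counts[v] += 1
    return max(counts.values(), default=0)


def parameter_panel(graph: GraphInstance, compute_k: bool = True) -> ParameterPanel:
    """Compute the full panel for a connected network instance."""
    from .dispatch import solve_tree  # deferred: dispatch imports params-free modules

    mto, _mapping, _auto = contract_to_tree(graph)
    base_root = min(mto.tree.vertices)
    rooted = build_rooted(mto.tree, base_root)

    cg, load = build_conflict_graph(mto, rooted)
    reduced = reduce_conflict_graph(cg)

    root_q, q_v = choose_root_min_qv(mto)
    q = len(cross_pair_index(mto, build_rooted(mto.tree, root_q)).Q)

    kept = sorted(reduced.nodes)
    reduced_mto = MTOInstance(mto.tree, [mto.pairs[i] for i in kept])
    # q' under the same rooting as q so that q' <= q; q_v' re-minimized
    q_prime = len(cross_pair_index(reduced_mto, build_rooted(mto.tree, root_q)).Q)
    _root_qp, q_v_prime = choose_root_min_qv(reduced_mto)

    max_deg = max((len(mto.tree.adj[v]) for v in mto.tree.vertices), default=0)

    k: int | None = None
    if compute_k:
        try:
            k = solve_tree(mto).unsatisfied_count
        except ValueError:
            k = None  # beyond solver caps

    panel = ParameterPanel(
        n=len(graph.vertices),
        m=len(graph.edges),
        p=len(graph.pairs),
        n_t=len(mto.tree.vertices),
        p_t=len(mto.pairs),
        n_star=1 + max_deg,
        m_v=_mv(mto, rooted),
        m_e=load.m_e,
        q=q,
        q_v=q_v,
        q_prime=q_prime,
        q_v_prime=q_v_prime,
        n_c=reduced.n_c,
        m_c=cg.m_c,
        k=k,
    )
    panel.check_invariants()
    return panel
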