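import math

import pytest

from treeorient.conflict import ConflictGraph, build_conflict_graph
from treeorient.generate import gen_instance
from treeorient.model import score_orientation
from treeorient.oracle import brute_force_solve
from treeorient.rooted import build_rooted
from treeorient.vc import (
    EliminationOrder,
    Tw2Failure,
    branch_vertex_cover,
    elimination_to_treedec,
    mv_decomposition,
    result_from_cover,
    solve_me2,
    treedec_vertex_cover,
    tw2_eliminate,
)

from .conftest import as_tree_instance


def _cg(edges, weights=None):
    nodes = {v for e in edges for v in e} | set(weights or {})
    return ConflictGraph(
        nodes=set(nodes),
        weights={v: (weights or {}).get(v, 1.0) for v in nodes},
        edges={tuple(sorted(e)) for e in edges},
    )


def _min_cover_brute(cg):
    """Subset enumeration: the reference minimum-weight vertex cover."""
    nodes = sorted(cg.nodes)
    best = math.inf
    for mask in range(1 << len(nodes)):
        cover = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
        if all(i in cover or j in cover for i, j in cg.edges):
            best = min(best, sum(cg.weights[v] for v in cover))
    return best


class TestBranchVertexCover:
    def test_triangle_needs_two(self):
        cover, weight = branch_vertex_cover(_cg([(0, 1), (1, 2), (0, 2)]))
        assert weight == 2.0 and len(cover) == 2

    def test_path_takes_middle(self):
        cover, weight = branch_vertex_cover(_cg([(0, 1), (1, 2)]))
        assert cover == {1} and weight == 1.0

    def test_weighted_single_edge(self):
        cover, weight = branch_vertex_cover(_cg([(0, 1)], weights={0: 5.0, 1: 1.0}))
        assert cover == {1} and weight == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_subset_enumeration(self, seed):
        inst = as_tree_instance(
            gen_instance("tree", 5 + seed % 4, 6, seed, weighted=(seed % 2 == 0))
        )
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        cg, _load = build_conflict_graph(inst, rooted)
        _cover, weight = branch_vertex_cover(cg)
        assert math.isclose(weight, _min_cover_brute(cg), abs_tol=1e-9)


class TestMvDecomposition:
    def test_cyclic_star_bags(self, cyclic_star):
        rooted = build_rooted(cyclic_star.tree, "r")
        cg, _load = build_conflict_graph(cyclic_star, rooted)
        td = mv_decomposition(cyclic_star, rooted, cg)
        assert td.bags["r"] == frozenset({0, 1, 2})
        assert td.bags["1"] == frozenset({0, 2})
        assert td.width == 2
        td.validate(cg)

    def test_path_instance_central_bag(self, path_abc):
        rooted = build_rooted(path_abc.tree, "a")
        cg, _load = build_conflict_graph(path_abc, rooted)
        td = mv_decomposition(path_abc, rooted, cg)
        assert td.bags["b"] == frozenset({0, 1, 2})
        assert td.width == 2

    def test_no_pairs_empty_bags(self):
        inst = as_tree_instance(gen_instance("tree", 5, 0, 0))
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        cg, _load = build_conflict_graph(inst, rooted)
        td = mv_decomposition(inst, rooted, cg)
        assert all(b == frozenset() for b in td.bags.values())

    @pytest.mark.parametrize("seed", range(15))
    def test_always_valid_with_width_mv_minus_one(self, seed):
        inst = as_tree_instance(gen_instance("tree", 4 + seed % 8, 6, seed))
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        cg, _load = build_conflict_graph(inst, rooted)
        td = mv_decomposition(inst, rooted, cg)
        td.validate(cg)
        m_v = max((len(b) for b in td.bags.values()), default=0)
        assert td.width == m_v - 1


class TestTreedecVertexCover:
    def test_triangle_single_bag(self):
        cg = _cg([(0, 1), (1, 2), (0, 2)])
        td_bags = {0: frozenset({0, 1, 2})}
        from treeorient.vc import TreeDecomposition

        td = TreeDecomposition(bags=td_bags, tree_edges=set())
        cover, weight = treedec_vertex_cover(cg, td)
        assert weight == 2.0 and len(cover) == 2

    def test_empty_graph(self):
        from treeorient.vc import TreeDecomposition

        cover, weight = treedec_vertex_cover(
            ConflictGraph(set(), {}, set()), TreeDecomposition({}, set())
        )
        assert cover == set() and weight == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_branching(self, seed):
        inst = as_tree_instance(
            gen_instance("tree", 5 + seed % 4, 6, seed, weighted=(seed % 3 == 0))
        )
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        cg, _load = build_conflict_graph(inst, rooted)
        td = mv_decomposition(inst, rooted, cg)
        cover, weight = treedec_vertex_cover(cg, td)
        _c2, w2 = branch_vertex_cover(cg)
        assert math.isclose(weight, w2, abs_tol=1e-9)
        # the returned set really is a cover of that weight
        assert all(i in cover or j in cover for i, j in cg.edges)
        assert math.isclose(sum(cg.weights[v] for v in cover), weight, abs_tol=1e-9)


class TestTw2Eliminate:
    def test_triangle_reduces(self):
        order = tw2_eliminate(_cg([(0, 1), (1, 2), (0, 2)]))
        assert isinstance(order, EliminationOrder)
        assert len(order.steps) == 3
        assert all(len(nbrs) <= 2 for _v, _r, nbrs in order.steps)

    def test_k4_fails(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        result = tw2_eliminate(_cg(edges))
        assert isinstance(result, Tw2Failure)
        assert result.remnant == {0, 1, 2, 3}

    def test_empty_graph_succeeds(self):
        order = tw2_eliminate(ConflictGraph(set(), {}, set()))
        assert isinstance(order, EliminationOrder) and order.steps == []

    def test_order_yields_valid_width2_decomposition(self):
        cg = _cg([(0, 1), (1, 2), (2, 3), (3, 0)])  # 4-cycle: treewidth 2
        order = tw2_eliminate(cg)
        assert isinstance(order, EliminationOrder)
        td = elimination_to_treedec(order)
        td.validate(cg)
        assert td.width <= 2


class TestSolveMe2:
    def test_cyclic_star(self, cyclic_star):
        rooted = build_rooted(cyclic_star.tree, "r")
        res = solve_me2(cyclic_star, rooted)
        assert res.satisfied_weight == 1.0 and res.unsatisfied_count == 2

    def test_single_pair(self):
        inst = as_tree_instance(gen_instance("tree", 6, 1, 2))
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        res = solve_me2(inst, rooted)
        assert res.unsatisfied_count == 0

    def test_high_edge_load_rejected(self, path_abc):
        rooted = build_rooted(path_abc.tree, "a")
        with pytest.raises(ValueError, match="m_e = 3"):
            solve_me2(path_abc, rooted)

    @pytest.mark.parametrize("seed", range(25))
    def test_bounded_load_instances_reduce_and_solve(self, seed):
        """Constructive treewidth-2 content: every m_e <= 2 instance
        eliminates fully, and the pipeline matches brute force."""
        inst = as_tree_instance(
            gen_instance("bounded_me", 5 + seed % 4, 3, seed, me_cap=2,
                         weighted=(seed % 2 == 0))
        )
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        cg, load = build_conflict_graph(inst, rooted)
        assert load.m_e <= 2
        assert isinstance(tw2_eliminate(cg), EliminationOrder)
        res = solve_me2(inst, rooted)
        expect = brute_force_solve(inst).satisfied_weight
        assert math.isclose(res.satisfied_weight, expect, abs_tol=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_proposition_chain_total_minus_cover_is_optimum(seed):
    """All vertex-cover routes yield total weight - cover = brute optimum,
    and the cover complement lifts to a consistent witness orientation."""
    inst = as_tree_instance(
        gen_instance("tree", 4 + seed % 5, 6, seed, weighted=(seed % 2 == 0))
    )
    rooted = build_rooted(inst.tree, min(inst.tree.vertices))
    cg, _load = build_conflict_graph(inst, rooted)
    opt = brute_force_solve(inst).satisfied_weight
    total = inst.total_pair_weight()
    cover_b, weight_b = branch_vertex_cover(cg)
    td = mv_decomposition(inst, rooted, cg)
    cover_t, weight_t = treedec_vertex_cover(cg, td)
    assert math.isclose(total - weight_b, opt, abs_tol=1e-9)
    assert math.isclose(total - weight_t, opt, abs_tol=1e-9)
    for cover, weight in ((cover_b, weight_b), (cover_t, weight_t)):
        res = result_from_cover(inst, rooted, cover, weight, "test")
        w, _sat = score_orientation(inst, res.orientation)
        assert math.isclose(w, opt, abs_tol=1e-9)
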