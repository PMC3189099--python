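import math

import pytest

from treeorient.dp import (
    CrossPairError,
    choose_root_min_qv,
    compute_A,
    compute_A_direct,
    cross_pair_index,
    find_crossfree_root,
    solve_crossfree,
    solve_crosspairs,
)
from treeorient.generate import gen_instance
from treeorient.model import MTOInstance, SourceTargetPair, TreeInstance, score_orientation
from treeorient.oracle import brute_force_solve
from treeorient.rooted import build_rooted

from .conftest import as_tree_instance


@pytest.fixture
def weighted_path():
    """Path a-b-c with pairs [a,b] w2, [b,a] w3, [a,c] w1."""
    tree = TreeInstance(["a", "b", "c"], [("a", "b"), ("b", "c")])
    pairs = [
        SourceTargetPair("a", "b", 2.0),
        SourceTargetPair("b", "a", 3.0),
        SourceTargetPair("a", "c", 1.0),
    ]
    return MTOInstance(tree, pairs)


class TestATable:
    def test_single_edge_base_case(self, weighted_path):
        rooted = build_rooted(weighted_path.tree, "a")
        A = compute_A(weighted_path, rooted)
        assert A("a", "b") == 2.0
        assert A("b", "a") == 3.0

    def test_extension_recurrence(self, weighted_path):
        rooted = build_rooted(weighted_path.tree, "a")
        A = compute_A(weighted_path, rooted)
        # pairs [a,b] and [a,c] both lie downward on path a..c
        assert A("a", "c") == 3.0
        assert A("c", "a") == 3.0
        assert A("b", "b") == 0.0

    def test_no_pairs_all_zero(self):
        inst = as_tree_instance(gen_instance("tree", 8, 0, 1))
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        A = compute_A(inst, rooted)
        assert all(v == 0.0 for v in A.values.values())

    @pytest.mark.parametrize("seed", range(15))
    def test_queue_equals_direct_summation(self, seed):
        """The single-edge-extension recurrence reproduces the explicit
        definition of A on random weighted trees."""
        inst = as_tree_instance(
            gen_instance("tree", 4 + seed % 12, 8, seed, weighted=True)
        )
        root = sorted(inst.tree.vertices)[seed % len(inst.tree.vertices)]
        rooted = build_rooted(inst.tree, root)
        fast = compute_A(inst, rooted)
        slow = compute_A_direct(inst, rooted)
        assert set(fast.values) == set(slow.values)
        for key, val in slow.values.items():
            assert math.isclose(fast.values[key], val, abs_tol=1e-9)


class TestCrossPairIndex:
    def test_cyclic_star_at_center(self, cyclic_star):
        rooted = build_rooted(cyclic_star.tree, "r")
        cpi = cross_pair_index(cyclic_star, rooted)
        assert cpi.Q == {0, 1, 2}
        assert cpi.q_v_of_root == 3  # all three paths pass through r

    def test_cyclic_star_at_leaf(self, cyclic_star):
        rooted = build_rooted(cyclic_star.tree, "1")
        cpi = cross_pair_index(cyclic_star, rooted)
        assert cpi.Q == {1}  # only [2, 3] remains a cross pair
        assert cpi.q_v_of_root == 1

    def test_path_rooted_at_endpoint_is_crossfree(self):
        inst = as_tree_instance(gen_instance("path", 6, 6, 2))
        endpoint = min(inst.tree.vertices)
        cpi = cross_pair_index(inst, build_rooted(inst.tree, endpoint))
        assert cpi.Q == set()


class TestRootSelection:
    def test_path_has_crossfree_endpoint_root(self):
        inst = as_tree_instance(gen_instance("path", 7, 6, 4))
        root = find_crossfree_root(inst)
        assert root is not None
        cpi = cross_pair_index(inst, build_rooted(inst.tree, root))
        assert cpi.Q == set()

    def test_cyclic_star_has_no_crossfree_root(self, cyclic_star):
        assert find_crossfree_root(cyclic_star) is None

    def test_min_qv_root_prefers_smallest_leaf(self, cyclic_star):
        assert choose_root_min_qv(cyclic_star) == ("1", 1)

    def test_no_pairs_returns_smallest_vertex(self):
        inst = as_tree_instance(gen_instance("tree", 5, 0, 0))
        assert find_crossfree_root(inst) == min(inst.tree.vertices)
        root, qv = choose_root_min_qv(inst)
        assert root == min(inst.tree.vertices) and qv == 0


class TestCrossfreeSolver:
    def test_weighted_path_optimum(self, weighted_path):
        rooted = build_rooted(weighted_path.tree, "a")
        res = solve_crossfree(weighted_path, rooted)
        assert res.satisfied_weight == 3.0

    def test_path_instance(self, path_abc):
        res = solve_crossfree(path_abc, build_rooted(path_abc.tree, "a"))
        assert res.satisfied_weight == 2.0 and res.unsatisfied_count == 1

    def test_cross_pair_rejected(self, cyclic_star):
        with pytest.raises(CrossPairError, match=r"\[2, 3\]"):
            solve_crossfree(cyclic_star, build_rooted(cyclic_star.tree, "1"))

    def test_no_pairs(self):
        inst = as_tree_instance(gen_instance("tree", 6, 0, 5))
        rooted = build_rooted(inst.tree, min(inst.tree.vertices))
        res = solve_crossfree(inst, rooted)
        assert res.satisfied_weight == 0.0
        assert len(res.orientation) == len(inst.tree.edges)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_oracle_on_crossfree_instances(self, seed):
        inst = as_tree_instance(
            gen_instance("crossfree", 4 + seed % 9, 6, seed, weighted=(seed % 2 == 0))
        )
        root = find_crossfree_root(inst)
        assert root is not None
        res = solve_crossfree(inst, build_rooted(inst.tree, root))
        expect = brute_force_solve(inst).satisfied_weight
        assert math.isclose(res.satisfied_weight, expect, abs_tol=1e-9)


class TestCrossPairSolver:
    def test_cyclic_star_from_leaf(self, cyclic_star):
        res = solve_crosspairs(cyclic_star, build_rooted(cyclic_star.tree, "1"))
        assert res.satisfied_weight == 1.0 and res.unsatisfied_count == 2

    def test_collapses_to_crossfree_solver(self, path_abc):
        rooted = build_rooted(path_abc.tree, "a")
        a = solve_crosspairs(path_abc, rooted)
        b = solve_crossfree(path_abc, rooted)
        assert a.satisfied_weight == b.satisfied_weight

    def test_qv_cap_enforced(self, cyclic_star):
        with pytest.raises(ValueError, match="q_v"):
            solve_crosspairs(cyclic_star, build_rooted(cyclic_star.tree, "r"), qv_cap=2)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_oracle_on_unrestricted_instances(self, seed):
        """Coloring DP equals brute force on random trees, with the table
        indexed at the q_v-minimizing root."""
        inst = as_tree_instance(
            gen_instance("tree", 4 + seed % 5, 6, seed, weighted=(seed % 2 == 0))
        )
        root, _qv = choose_root_min_qv(inst)
        res = solve_crosspairs(inst, build_rooted(inst.tree, root))
        expect = brute_force_solve(inst).satisfied_weight
        assert math.isclose(res.satisfied_weight, expect, abs_tol=1e-9)
        w, _sat = score_orientation(inst, res.orientation)
        assert math.isclose(w, res.satisfied_weight, abs_tol=1e-9)

    def test_weight_scaling_equivariance(self):
        inst = as_tree_instance(gen_instance("tree", 7, 6, 11, weighted=True))
        root, _ = choose_root_min_qv(inst)
        rooted = build_rooted(inst.tree, root)
        base = solve_crosspairs(inst, rooted).satisfied_weight
        scaled_inst = MTOInstance(
            inst.tree,
            [SourceTargetPair(p.source, p.target, 3.0 * p.weight) for p in inst.pairs],
        )
        scaled = solve_crosspairs(scaled_inst, rooted).satisfied_weight
        assert math.isclose(scaled, 3.0 * base, abs_tol=1e-9)

    def test_coloring_table_size_bound(self, cyclic_star):
        rooted = build_rooted(cyclic_star.tree, "r")
        cpi = cross_pair_index(cyclic_star, rooted)
        for v in cyclic_star.tree.vertices:
            assert 2 ** len(cpi.Q_v[v]) <= 2 ** cpi.q_v_of_root
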