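import pytest
from hypothesis import settings

from treeorient.model import GraphInstance, MTOInstance, SourceTargetPair, TreeInstance

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from treeorient.preprocess import contract_to_tree


@pytest.fixture
def path_abc():
    """Path a-b-c with pairs [a,c], [c,a], [a,b]: one pair must fail."""
    tree = TreeInstance(["a", "b", "c"], [("a", "b"), ("b", "c")])
    pairs = [
        SourceTargetPair("a", "c"),
        SourceTargetPair("c", "a"),
        SourceTargetPair("a", "b"),
    ]
    return MTOInstance(tree, pairs)


@pytest.fixture
def cyclic_star():
    """Star with center r, leaves 1-3, cyclically conflicting pairs."""
    tree = TreeInstance(["r", "1", "2", "3"], [("r", "1"), ("r", "2"), ("r", "3")])
    pairs = [
        SourceTargetPair("1", "2"),
        SourceTargetPair("2", "3"),
        SourceTargetPair("3", "1"),
    ]
    return MTOInstance(tree, pairs)


@pytest.fixture
def triangle_pendant():
    """Triangle {x,y,z} plus pendant edge w-x; pairs [w,y] and [y,z]."""
    return GraphInstance(
        {"w", "x", "y", "z"},
        {("x", "y"), ("y", "z"), ("x", "z"), ("w", "x")},
        [SourceTargetPair("w", "y"), SourceTargetPair("y", "z")],
    )


def as_tree_instance(graph: GraphInstance) -> MTOInstance:
    mto, _mapping, _auto = contract_to_tree(graph)
    return mto
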