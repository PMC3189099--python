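"""Rooted tree index with constant-time lowest-common-ancestor queries.

The index is built once per rooting: an Euler tour of the tree is recorded
together with vertex depths, and a sparse table answers range-minimum
queries over the tour, which is the classical reduction of LCA to RMQ.
Children lists are kept in lexicographic order so every traversal in the
package is deterministic.
"""

from __future__ import annotations

from .model import InstanceError, TreeInstance

__all__ = ["RootedTree", "build_rooted"]


class RootedTree:
    """Parent/depth/children structure plus an Euler-tour LCA index."""

    def __init__(self, tree: TreeInstance, root: str):
        if root not in tree.vertices:
            raise KeyError(f"root {root!r} is not a tree vertex")
        self.tree = tree
        self.root = root
        self.parent: dict[str, str | None] = {root: None}
        self.depth: dict[str, int] = {root: 0}
        self.children: dict[str, list[str]] = {}
        self.order: list[str] = []  # preorder

        stack = [root]
        while stack:
            v = stack.pop()
            self.order.append(v)
            kids = [u for u in tree.adj[v] if u != self.parent[v]]
            self.children[v] = kids  # adjacency lists are pre-sorted
            for u in reversed(kids):
                self.parent[u] = v
                self.depth[u] = self.depth[v] + 1
                stack.append(u)
        if len(self.order) != len(tree.vertices):
            raise InstanceError("rooting did not reach every vertex")

        self._build_euler()

    # -- Euler tour + sparse table --------------------------------------
    def _build_euler(self) -> None:
        tour: list[str] = []
        first: dict[str, int] = {}
        # iterative Euler tour: push (vertex, child cursor)
        stack: list[tuple[str, int]] = [(self.root, 0)]
        while stack:
            v, i = stack.pop()
            if i == 0:
                first.setdefault(v, len(tour))
            tour.append(v)
            kids = self.children[v]
            if i < len(kids):
                stack.append((v, i + 1))
                stack.append((kids[i], 0))
        self._tour = tour
        self._first = first
        depths = [self.depth[v] for v in tour]
        # sparse table of argmin positions over the depth sequence
        m = len(tour)
        log = [0] * (m + 1)
        for i in range(2, m + 1):
            log[i] = log[i // 2] + 1
        self._log = log
        table = [list(range(m))]
        j = 1
        while (1 << j) <= m:
            prev = table[j - 1]
            span = 1 << (j - 1)
            row = []
            for i in range(m - (1 << j) + 1):
                a, b = prev[i], prev[i + span]
                row.append(a if depths[a] <= depths[b] else b)
            table.append(row)
            j += 1
        self._table = table
        self._depths = depths

    def lca(self, u: str, v: str) -> str:
        """Deepest common ancestor of u and v; ``lca(v, v) == v``."""
        try:
            i, j = self._first[u], self._first[v]
        except KeyError as exc:
            raise KeyError(f"vertex {exc.args[0]!r} is not in the tree") from None
        if i > j:
            i, j = j, i
        k = self._log[j - i + 1]
        a = self._table[k][i]
        b = self._table[k][j - (1 << k) + 1]
        pos = a if self._depths[a] <= self._depths[b] else b
        return self._tour[pos]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff a is an ancestor of b (or a == b)."""
        return self.lca(a, b) == a

    def distance(self, u: str, v: str) -> int:
        a = self.lca(u, v)
        return self.depth[u] + self.depth[v] - 2 * self.depth[a]

    def postorder(self) -> list[str]:
        return list(reversed(self.order))


def build_rooted(tree: TreeInstance, root: str) -> RootedTree:
    """Root ``tree`` at ``root`` and build the LCA index."""
    return RootedTree(tree, root)
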