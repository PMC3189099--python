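# treeorient

Exact orientation of undirected networks for cause–effect pairs.

## The problem

Protein–protein interaction screens report *undirected* edges, while gene
knockout experiments yield ordered cause–effect pairs: perturbing protein
*s* changes the expression of *t*, so information must be able to flow from
*s* to *t*. Reconciling the two means choosing a direction for every edge
of the network so that as many pairs as possible are connected by a
directed path.

Formally, given an undirected graph *G* = (*V*, *E*) and weighted ordered
pairs *P* ⊆ *V* × *V* with ω([s,t]) ≥ 0, an orientation replaces each edge
{u,v} by one arc; a pair [s,t] is *satisfied* if the oriented graph has a
directed s→t path. The goal is an orientation maximizing the total weight
of satisfied pairs (equivalently, minimizing the weight *k* of unsatisfied
pairs). The problem is NP-hard even on stars, but every 2-edge-connected
block can be oriented as a directed cycle and contracted, so it suffices to
solve the problem on a tree. `treeorient` implements this contraction and a
portfolio of exact, fixed-parameter solvers for the tree problem:

* **conflict graph + vertex cover** — two pairs *conflict* when their tree
  paths cross some edge in opposite directions; the unsatisfied pairs of any
  orientation form a vertex cover of the conflict graph G_c, so the optimum
  is (total weight) − (minimum-weight vertex cover of G_c). Covers are found
  by branch-and-bound, or by subset dynamic programming over a tree
  decomposition: the input tree with bags P_v (pairs through vertex v) is a
  decomposition of G_c of width m_v − 1.
* **cross-pair-free dynamic program** — under a rooting where every pair
  runs purely up or purely down (no *cross pairs*), a table
  S(v,w) = A(v,w) + Σ_{u child of w} max{ S(u,w), S(v,u) − A(v,w) }
  solves the problem in O(n²), where A(v,w) is the weight of pairs carried
  by the v→w path itself. Paths rooted at an endpoint are always
  cross-pair-free.
* **cross-pair coloring dynamic program** — in general each table slice at
  w is extended by a 0/1 coloring of the cross pairs through w (1 = must be
  satisfiable), giving an O(2^{q_v} · q_v · n²) algorithm in the maximum
  number q_v of cross pairs per vertex.
* **bounded edge load** — if no edge carries more than two pair paths
  (m_e ≤ 2), the conflict graph has treewidth ≤ 2 and reduces to the empty
  graph by degree-0/1 deletion, triangle deletion, and series contraction;
  the recorded elimination yields a width-2 decomposition and a direct
  solve. For m_e ≥ 3 the problem is already NP-hard (stars encode maximum
  directed cuts).

Every solver returns a witness orientation that is re-scored against the
instance before it is reported, and a brute-force enumerator over all
2^|E| orientations serves as the reference implementation throughout the
test suite.

## Worked example

Generate a 6-vertex star with 6 unit-weight pairs and solve it:

```sh
$ treeorient generate --kind star --n 6 --pairs 6 --seed 11 --out-prefix star
$ treeorient solve --edges star.edges.tsv --pairs star.pairs.tsv --verbose
# n=6 m=5 p=6 n_t=6 p_t=6 algorithm=crosspairs
{
  "satisfied_weight": 4.0,
  "unsatisfied_weight": 2.0,
  "auto_satisfied_weight": 0.0,
  "k": 2,
  "satisfied_pairs": [0, 1, 3, 5],
  "algorithm": "crosspairs"
}
```

The instance has no cycles (`n_t`, `p_t` match `n`, `p`), no cross-pair-free
rooting exists and some edge carries three pair paths, so the dispatcher
picks the coloring DP. At most 4 of the 6 pairs can be satisfied
simultaneously (`k = 2` must fail), and `satisfied_pairs` indexes the
normalized pair list. The structural parameters behind that choice:

```sh
$ treeorient params --edges star.edges.tsv --pairs star.pairs.tsv
{ "n": 6, "m": 5, "p": 6, "n_t": 6, "p_t": 6, "n_star": 6,
  "m_v": 6, "m_e": 3, "q": 3, "q_v": 3, "q_prime": 1, "q_v_prime": 1,
  "n_c": 4, "m_c": 3, "k": 2 }
```

Here m_v/m_e are the maximum pair paths per vertex/edge, q and q_v count
cross pairs (q′, q_v′ after dropping pairs that conflict with nothing),
n_c/m_c are conflict-graph sizes, and k is the exact optimum. The same
functionality is available from Python:

```python
from treeorient import read_instance, solve_dispatch

graph = read_instance("star.edges.tsv", "star.pairs.tsv")
result = solve_dispatch(graph)           # contract, solve, lift back
print(result.satisfied_weight, result.unsatisfied_count)  # 4.0 2
```

Other subcommands: `contract` (bridge-block tree and vertex mapping),
`conflicts` (the conflict graph as pair-index edges), and
`solve --algorithm brute|crossfree|crosspairs|vc-branch|vc-treedec|me2`
to force a particular solver; all solvers agree on the optimum.

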