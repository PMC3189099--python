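# Methods

## Model

An instance is an undirected graph *G* = (*V*, *E*) with a list of ordered
source–target pairs, each carrying a nonnegative rational weight (default
1). An orientation assigns one direction per edge; a pair [s, t] is
satisfied when a directed s→t path exists. The optimization target is the
total satisfied weight; the complementary quantity *k* (number of
unsatisfied pairs in the optimal witness) is reported alongside.

Input normalization: duplicate pairs are merged by summing weights, and
pairs with source = target are removed and booked as satisfied by any
orientation. Both transformations preserve the set of optimal
orientations. Vertex identifiers are opaque strings; no numeric structure
is assumed.

## Bridge-block contraction

Any cycle can be oriented as a directed cycle, which makes each
2-edge-connected block strongly connectable without sacrificing any pair.
The solver therefore contracts each bridge block to a single tree vertex
(bridges become tree edges) and solves the tree instance. Pairs whose
endpoints land in the same block are satisfied for free and their weight
is accounted separately. Orientations are lifted back by giving each
bridge its tree direction and orienting each nontrivial block with a
depth-first search: spanning-tree arcs point away from the root of the
search, every non-tree edge is a back edge and points from descendant to
ancestor. For 2-edge-connected graphs this is strongly connected (the
constructive direction of Robbins' theorem), which the test suite checks
by reachability. Bridge finding and connectivity checks are delegated to
networkx. Disconnected inputs are rejected with a component listing rather
than solved per component, keeping one instance = one connected network.

Block naming is deterministic: a singleton block keeps its vertex id, a
nontrivial block is named `B` + its lexicographically smallest member
(with `_` appended on the rare name clash).

## Conflict graph and the vertex-cover equivalence

Two pairs conflict exactly when their tree paths traverse a common edge in
opposite directions; no orientation can satisfy both. The conflict graph
G_c has the pairs as nodes and conflicts as edges. In any orientation the
satisfied pairs are pairwise conflict-free, so the unsatisfied pairs form
a vertex cover of G_c; conversely the complement of any vertex cover is
simultaneously satisfiable (pairwise compatibility suffices, because each
pair constrains exactly the edges of its own path). Minimum-weight vertex
cover on G_c therefore gives the optimum, and a witness orientation is
rebuilt by orienting every satisfied pair's path in its own direction and
the remaining edges low-endpoint→high-endpoint.

Construction is by edge marking: every pair stamps the edges of its path
with its direction relative to the rooting (parent→child = down), and each
(down, up) combination on an edge yields a conflict; the edge set is
deduplicated. The pairwise all-pairs construction exists as a test oracle
only, and both are validated against joint-orientation enumeration on
random instances. The per-pair conflict predicate compares directed edge
sets of the two paths, an O(path length) test rather than a constant-time
LCA-incidence test; at the problem sizes this package targets the
difference is immaterial, and the two criteria define the same relation.

Pairs that conflict with nothing can be dropped (they are satisfiable
jointly with any optimum); the reduced node count is the parameter n_c.

## Dynamic programs

### Path-weight table A

For a rooted tree and vertices v ⪯ w, A(v, w) is the weight of pairs with
both endpoints on the v..w path that are satisfied when the path is
oriented downward v→w, and A(w, v) the same for the upward direction
(A(v, v) = 0). A is filled in O(n²) by single-edge extension: with x the
child of v toward w and y the parent of w,

    A(v, w) = ω([v, w]) + A(v, y) + A(x, w) − A(x, y),

processing vertices root-down so all shorter paths are available. The
direct-summation definition is kept as a test oracle.

### Cross-pair-free instances

A pair is a *cross pair* under a rooting if neither endpoint is an
ancestor of the other. If a rooting with no cross pairs exists (found in
O(n·|P|) by testing every root; paths rooted at an endpoint always
qualify), the problem is solved by a quadratic DP. S(v, w) is the best
weight on the subtree T_w plus the v..w path, with the path oriented
v→w; S(w, v) fixes the opposite direction; S(v, v) covers the subtree at
v. Bottom-up over w, for every ancestor v:

    S(v, w) = A(v, w) + Σ_{u child of w} max{ S(u, w), S(v, u) − A(v, w) }

and symmetrically for S(w, v); the optimum is S(r, r). The subtraction
removes the path-pair weight already counted by the parent entry.

### Cross-pair coloring DP

In general each table slice at w is indexed by a 0/1 coloring of Q_w, the
cross pairs whose path passes through w (the global bit order is ascending
pair index). Color 1 means "must remain satisfiable". An entry
S(v, w, c_w) is −∞ when the coloring is infeasible: two 1-colored cross
pairs conflict, or a 1-colored cross pair's path cannot be co-oriented
with the fixed v→w (or w→v) path direction. Otherwise

    S(v, w, c_w) = A(v, w) + W_LCA(w, c_w) + Σ_i M(u_i, v, w, c_w),

where W_LCA credits 1-colored cross pairs at their lowest common ancestor
(the one vertex where both halves of the pair have been decided) and each
child maximum M ranges over the child's orientation branch and over all
child colorings that agree with c_w on the shared cross pairs Q_u ∩ Q_w.
Agreement is resolved by bucketing each child's colorings by their
restriction to the shared set, built once per tree edge. The optimum is
max over c_r of S(r, r, c_r). With q_v(r) = max_w |Q_w| the table has at
most 2^{q_v(r)} slices per entry; the solver refuses q_v(r) > 22, and the
dispatcher first picks the root minimizing q_v(r) (ties to the smallest
vertex id). A cross-pair-free rooting degenerates to the previous DP
(every coloring set is the singleton empty coloring).

−∞ is `float("-inf")`, which absorbs addition and loses every maximum, so
the recurrence needs no special cases.

### Witness traceback

The recurrences above only produce weights, so every table entry records,
per child, which branch (and which child coloring) attained the maximum.
The orientation is rebuilt root-down — each visited entry orients its own
v..w path — and then re-scored against the instance; the re-scored value
is asserted equal to the DP optimum and is the value reported. Ties in
every argmax are broken toward the first candidate in a fixed
deterministic iteration order (children in lexicographic order, colorings
in ascending mask order), so repeated runs return identical witnesses.

## Vertex-cover solvers

* **Branch and bound**: branch on a maximum-degree node (smallest index on
  ties): either it joins the cover or its whole neighborhood does. Under
  uniform weights, degree-1 nodes are first eliminated by taking their
  neighbor; for general weights this rule is not weight-safe and is
  disabled, the branching itself remains exact. The second branch is
  pruned when the accumulated weight reaches the incumbent.
* **m_v decomposition**: the input tree with bags P_v is a valid tree
  decomposition of G_c of width m_v − 1 (conflicting pairs share an edge,
  so every conflict edge lies in a bag; each pair occupies the contiguous
  set of bags along its own path). It is converted to a nice decomposition
  (leaf/introduce/forget/join) and solved by the standard subset DP:
  introduce nodes enforce intra-bag edge coverage, forget nodes commit a
  node's fate (recorded for cover reconstruction), join nodes add tables
  and subtract the double-counted bag weight.
* **m_e ≤ 2 pipeline**: when no edge carries more than two pair paths the
  conflict graph has treewidth ≤ 2 and the three classical reduction rules
  (delete degree ≤ 1; delete a degree-2 node with adjacent neighbors; join
  the neighbors of a degree-2 node and delete it) empty it. Rules are
  applied to the lowest-index applicable node, rules tried in order 1, 2,
  3, making the elimination order deterministic. Replaying the order in
  reverse yields a width-≤ 2 decomposition (each deleted node's bag is
  itself plus its neighbors at deletion time, attached to an existing bag
  containing those neighbors), which feeds the same decomposition DP. The
  elimination operates directly on the conflict graph; rewriting the tree
  instance itself is unnecessary for solving. m_e > 2 is rejected with the
  violating edge named — for m_e ≥ 3 no comparable structure exists (stars
  with m_e = 3 already encode maximum directed cut).

## Parameter panel

The panel reports n, m, p for the input graph; n_t, p_t after contraction;
n\* = 1 + maximum tree degree (the "star size" of hub-dominated networks);
m_v, m_e; cross-pair counts q, q_v, and q′, q_v′ after dropping
conflict-free pairs; conflict-graph sizes n_c (nodes with at least one
conflict) and m_c; and optionally the exact k from the auto-dispatched
solver. Cross-pair counts are rooting-dependent: q_v is minimized over all
roots, and q is reported under that same minimizing root, as is q′ (so
that q′ ≤ q holds structurally); q_v′ is re-minimized for the reduced pair
set. m_v and m_e are rooting-independent.

## Solver dispatch

`solve_dispatch` contracts, then picks: cross-pair-free rooting exists →
quadratic DP; else m_e ≤ 2 → elimination pipeline; else q_v ≤ 16 →
coloring DP; else m_v ≤ 20 → decomposition vertex cover; else branch and
bound. The two thresholds bound table sizes (2^{q_v} colorings, 2^{m_v}
bag subsets) to sub-minute interactive runs and are overridable
parameters, not properties of the method. The brute-force enumerator
(≤ 20 edges) is exposed as an explicit algorithm choice for
cross-checking.

## Synthetic data

The generators produce the instance families the solvers specialize to:
uniform random labeled trees (Prüfer decoding), stars with leaf-to-leaf
pairs, paths, cross-pair-free instances (pairs drawn along ancestor lines
of a fixed root, direction uniform), bounded-edge-load instances (pairs
rejection-sampled under a per-edge cap, erroring when the cap is
infeasible after 500 attempts per pair), random connected cyclic graphs
(random tree plus chords), and star instances derived from random
digraphs, whose optimum equals the digraph's maximum directed cut. Pair
endpoints are drawn uniformly over distinct ordered pairs; weighted mode
draws integer weights uniformly from 1–10, covering weight-tie and
weight-dominance behavior without floating-point noise. Each generator
owns a `random.Random(seed)`; identical seeds give byte-identical
instances.

These families deliberately do **not** reproduce the degree distribution,
hub structure, or pair correlations of real interaction networks (real
instances are dominated by one high-degree hub and thousands of pairs
through it). Passing tests therefore certify algorithmic correctness —
every solver route agrees with exhaustive enumeration on its applicable
family — not performance or biological fidelity on production-scale
networks. Real networks enter through the TSV reader and the same code
paths; the panel's caps report, rather than hide, when an instance is out
of reach of a given route.

## Numerical choices

* Weights are IEEE doubles parsed from decimal text; comparisons use
  absolute tolerance 1e−9 (weights are user-scale rationals, typically
  small integers).
* Brute-force and DP optima are compared exactly in tests up to 1e−9; the
  witness re-score assertion uses 1e−6 to tolerate summation-order
  effects across long accumulation chains.
* All argmax/tie decisions (enumeration order of orientations, child
  order, coloring order, elimination order, block naming) are fixed and
  documented above, so every solver is deterministic given its input.
* Degenerate inputs: single-vertex trees (no edges, empty orientation),
  empty pair lists (optimum 0), and pairs internal to one block are all
  handled explicitly and covered by tests.

## Problem sizes in the test and acceptance runs

The suite validates solvers against enumeration at sizes where
enumeration is airtight: trees up to 12 vertices for the cross-pair-free
DP, 8 for the coloring DP, 9–10 pair lists of up to 6–8 pairs, connected
graphs with up to 9 edges (2^9 orientations with reachability), digraphs
with up to 8 vertices (2^8 cuts), 100 seeds per family in the acceptance
checks and 20–50 in unit property tests. These sizes exercise every code
path (all rules, both DP cases, joins in the nice decomposition) while
keeping the whole suite in a few seconds.

## Known limitations

* The coloring DP's child-coloring scan is comparison/bucket based per
  parent coloring; its practical complexity carries an extra factor over
  the theoretical bucket-sort formulation, irrelevant at the supported
  q_v ≤ 22 but visible near the cap.
* The conflict-test shortcut and the LCA index target correctness, not
  the literature's linear-time bounds (Euler tour + sparse table is
  O(n log n) preprocessing).
* Mixed graphs with pre-oriented edges, length-bounded paths,
  approximation modes, enumeration of all optimal orientations, and ILP
  backends are out of scope.
* One instance per connected component: the caller splits disconnected
  networks (pairs across components are unsatisfiable anyway).
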