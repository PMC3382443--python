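# Methods

## Problem and scope

Given a finite simple graph G = (V, E), cliquekit solves maximum clique
enumeration (MCE): list every clique of size ω(G), the clique number.  The
intended inputs are thresholded correlation graphs from transcriptomic
experiments, whose maximum cliques overlap heavily; all algorithms also work
on arbitrary simple graphs.  Out of scope by design: breadth-first
(iterative) maximal-clique enumeration, approximate/top-N clique search,
weighted cliques inside the algorithms, and any GEO download tooling — the
synthetic test kit replaces external data entirely.

## Graph representation

Labels are kept externally (strings in all file formats; any totally ordered
hashable works programmatically) and mapped to dense 0-based indices
internally; adjacency is one frozenset of indices per vertex.  Every
iteration over vertices or neighbours is in ascending index order and index
order follows a numeric-aware label sort, so node counts, outputs and logs
are bit-reproducible across runs and platforms.  Graphs are value-semantic:
`remove_vertex`/`subgraph` return new graphs.

The edge-list format is one whitespace-separated pair per line with `#`
comments; a single-token line declares an isolated vertex, and the writer
emits such lines, so read∘write round-trips any graph (threshold graphs keep
isolated probes).  DIMACS ASCII clique format (`p edge n m`, `e u v`,
1-based) is read and written with a strict header/edge-count consistency
check.

## Bron–Kerbosch backtracking

The pivoting variant of the three-set recursion: COMPSUB (current clique),
CANDIDATES (vertices adjacent to all of COMPSUB, unexplored), NOT (explored;
suppresses duplicate maximal cliques).  A node emits COMPSUB exactly when
both CANDIDATES and NOT are empty.  Branch pruning: if some NOT vertex is
adjacent to every candidate, the subtree cannot emit.  The pivot rule makes
that happen as early as possible — the vertex of CANDIDATES ∪ NOT with the
most neighbours inside CANDIDATES is fixed and only candidates outside its
neighbourhood are branched on, ties broken by lowest index.  Per-call child
sets are restricted to the branch vertex's neighbourhood, so memory is
O(n · depth).  Cliques stream to a consumer; nothing is retained unless the
caller collects (output cost dominates enumeration in practice).  The node
counter counts recursive calls and is deterministic.

## Maximum Clique Finder (MCF)

1. **Greedy lower bound**: start from the highest-degree vertex and its
   highest-degree neighbour, repeatedly add the highest-degree vertex
   adjacent to the whole clique (degrees taken in G, ties by lowest index)
   until none remains.  Gives k = |C| ≤ ω(G); on an edgeless graph the
   degenerate answer is a single vertex.
2. **Preprocessing**: vertices of degree < k − 1 are peeled to a fixed point
   (tag `low_degree`); vertices adjacent to all others are moved to a forced
   list (tag `universal`, re-applied as extraction shrinks n) — they belong
   to every maximum clique, and ω(G) = ω(residual) + |forced|; greedy
   colouring of each closed neighbourhood (largest-degree-first, first-fit,
   ties by lowest index) removes any vertex whose neighbourhood admits fewer
   than k colours (tag `color`), repeated until a pass removes nothing.
   Colour exclusion runs at the root only by default: per-node colouring on
   small residuals costs more than it prunes.
3. **Branching**: in/out recursion on the candidate set (candidates are
   common neighbours of the current clique).  At every node the low-degree
   and universal rules are re-applied to the candidate set, plus the degree
   n − 2 rule: a candidate with a lone non-neighbour lets us discard that
   non-neighbour, because any clique through the non-neighbour maps to one
   of equal size through the candidate.  A node is cut when
   |clique| + |candidates| ≤ best-so-far.  Branch vertex: most neighbours
   among candidates, lowest index on ties; the "in" branch is explored
   first.  The greedy clique minus forced vertices survives every reduction,
   so it seeds the bound and the search only has to beat it.

The n − 2 rule and the strict cut are valid only because a *single* witness
is wanted; both are changed in enumeration mode (below).  The lower bound k
is not re-derived at internal nodes; it rises only when branching finds a
larger clique.

## The three MCE strategies

* **basic** — run Bron–Kerbosch, keep the largest cliques.  The benchmark.
* **intelligent** — compute k = ω(G) with MCF, colour-reduce the graph with
  that k, then run Bron–Kerbosch with an extra cut: return from any node
  with |COMPSUB| + |CANDIDATES| < k.  The NOT-based pruning is kept; the
  k-cut is an addition, not a replacement.  Every emitted maximal clique
  then has size exactly k.  Its node counter counts only the backtracking
  recursion, so it is directly comparable with basic.
* **parameterized** — MCF's branching in "all" mode: the bound admits ties
  (cut only when |clique| + |candidates| < best), the n − 2 rule is disabled
  (it silently discards cliques through the removed vertex — the 4-cycle,
  where every vertex has degree n − 2 and all four edges are maximum
  cliques, is the canonical counterexample), and a global list of the
  largest cliques found so far is flushed whenever a larger one appears.
  Root preprocessing keeps only the enumeration-safe rules (low-degree at
  the greedy bound, universal extraction); forced vertices are re-attached
  to every output clique.  Emitted member-sets are canonicalised and
  set-deduplicated.

All three return an `EnumerationResult` with k, the canonical clique
collection, the node count, and a status that becomes `halted` when a
caller-supplied node budget runs out (the hardware-independent stand-in for
wall-clock limits); a halted run returns whatever it had found.

## Reductions

`mcc_cover` greedily extracts pairwise-disjoint maximum cliques (each via
MCF on the residual) until the residual clique number drops; the union is a
maximum clique cover.  `mcc_reduce` deletes vertices neither in the cover
nor adjacent to it.  `essential_set` uses the characterisation
ω(G) > ω(G − v) ⇔ v lies in every maximum clique, and tests only the
members of one found maximum clique (essential vertices must lie in it), so
it costs k + 1 finder calls instead of n + 1.  `es_reduce` removes, in one
pass against the original graph, every non-neighbour of every essential
vertex; a `fixed_point` flag re-iterates, purely as an optimisation, since
one pass already preserves all maximum cliques.  MCC typically reduces
little (cover vertices touch much of the graph, and the finder's own rules
subsume the rest); the essential-set reduction is the one that bites.

## Correlation graph construction

Pearson correlations are computed over pairwise-complete conditions
(pandas, `min_periods=3`); pairs with support < 3 or zero variance are
omitted and logged rather than erroring.  P-values use the two-sided t
transform, t = |r|·sqrt((s − 2)/(1 − r²)) with s − 2 degrees of freedom
(p = 0 at |r| = 1).  Thresholding is inclusive: correlation ≥ t, p-value
≤ t.  Signed correlations are thresholded by default; |r| thresholding is
opt-in.  The log transform is base 2 by default (configurable) and rejects
non-positive values, naming the probe and condition.  Fewer than 12
conditions triggers a prominent warning (error under `strict=True`) —
correlations over so few conditions threshold unreliably — but toy inputs
still run.  Self-pairs never produce edges.

## Synthetic test kit

* `moon_moser(q)`: complete q-partite graph, parts of 3; its maximal
  cliques are exactly the 3^q transversals — the extremal family for the
  3^(n/3) bound, used to pin worst-case counting.
* `satellite_graph(perturbed)`: K5 on {1..5} plus satellites 6~{1,2,3},
  7~{2,3,4}, 8~{3,4,5} (a fixed attachment map; the satellites are mutually
  non-adjacent).  Pristine: unique maximum clique of size 5.  Perturbed
  (edge {1,2} deleted): four maximum cliques of size 4 — the worked example
  of single-edge sensitivity.  The derived count of 4 is tied to this
  attachment map.
* `planted_overlap(spec)`: `num_cliques` cliques of `clique_size` sharing
  exactly a `core_size`-vertex core, private parts disjoint, background
  edges i.i.d. with probability `background_p`.  Ground truth is enforced by
  rejection sampling: each draw is validated (brute force to n = 24,
  Bron–Kerbosch above) and redrawn from a fresh substream until the planted
  cliques are exactly the maximum cliques.  This emulates the overlapping
  dense region of real co-expression graphs.
* `degree_weighted_random(degrees, seed)`: Chung–Lu expected-degree model,
  P(u~v) = d_u·d_v / Σd capped at 1; requires max(d)² ≤ Σd.
  `power_law_degrees` samples P(d) ∝ d^−γ on [d_min, d_max] and clips the
  largest degrees until the validity condition holds.
* `brute_force_maximal`: breadth-first level-wise clique growth with a
  maximality check, guarded to n ≤ 25 — a different algorithm family from
  the backtracking it verifies.

What the generators do **not** emulate: real probe degree sequences,
correlation noise structure, or graph sizes in the tens of thousands of
vertices.  Passing tests therefore certify algorithmic correctness and the
qualitative planted-vs-random contrast, not runtime behaviour at
transcriptome scale.

## Problem sizes used in the test suite

The randomized equivalence suite uses 200 G(n, p) graphs with
n ∈ {12, 16, 20} and p ∈ {0.3, 0.5, 0.7} (fixed seeds), small enough for
the brute-force oracle to provide exact ground truth for every assertion.
Planted-recovery uses 25 specs at n = 24 (brute-force-validated).  The
random-contrast check draws 20 Chung–Lu graphs at n = 500 with power-law
exponent 2.5 and compares them with planted graphs at the same empirical
edge density (clique size 20): the random draws never exceed ω = 6 — a
seeded property of this kit's draws — while the planted graphs always
attain their planted size.

## Numerical and degenerate-input choices

Ties everywhere break on the lowest internal index.  ω of the empty graph
is 0 with an empty clique collection; an edgeless graph has ω = 1 and every
singleton is a maximum clique.  Correlations are clipped to [−1, 1] before
the t transform.  Thresholds are validated against the weight kind's range.
Node budgets count recursive calls, so `--budget-nodes 1` halts on any
graph that needs actual branching.

## Known limitations

Pure-Python kernels: at transcriptome scale (10⁴–10⁵ vertices) the
constant factors matter and a compiled adjacency-bitset kernel would be the
next step.  The pivot rule is this package's own deterministic choice —
node-count comparisons are meaningful within the package, not against other
implementations.  `essential_set` costs k + 1 full finder calls; on graphs
where MCF itself is slow, the reduction's overhead can exceed its benefit
(expected for easy instances).  The p-value path applies no
multiple-testing correction by design.
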