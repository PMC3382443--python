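# cliquekit

Maximum clique **enumeration** (MCE) for graphs built from high-throughput
expression data — and for any other simple undirected graph.

Gene co-expression analysis turns an expression matrix (probes × conditions)
into a graph: vertices are probes, and two probes are joined when the Pearson
correlation of their expression profiles is at or above a threshold *t* (at or
below *t* when correlation p-values are used instead).  A maximum clique in
that graph is a densest putative interaction module — but graphs usually have
*many* maximum cliques, and picking one arbitrarily makes downstream analyses
irreproducible.  cliquekit finds **all** of them.

## What is inside

Let ω(G) denote the clique number of G (the size of a maximum clique).

* **Bron–Kerbosch backtracking** (`enumerate_maximal`) — the classical
  COMPSUB / CANDIDATES / NOT recursion with pivot pruning, enumerating every
  maximal clique.  Worst-case optimal: a graph can hold 3^(n/3) maximal
  cliques, and the complete multipartite family with parts of size 3
  (`moon_moser`) attains the bound.
* **Maximum Clique Finder** (`find_maximum_clique`) — one maximum clique and
  ω(G) by fixed-parameter-style in/out vertex branching after greedy
  lower-bounding, low-degree peeling, universal-vertex extraction and
  greedy-colouring exclusion.
* **Three MCE strategies** (`enumerate_maximum_{basic,intelligent,parameterized}`)
  — filter all maximal cliques; prune the backtracking with the precomputed
  k = ω(G) (any node with |COMPSUB| + |CANDIDATES| < k returns immediately);
  or re-use the finder's own branching with a flush-on-larger global clique
  list.  All three provably return the same clique set.
* **Reductions** (`es_reduce`, `mcc_reduce`) — a *maximum clique cover* is a
  vertex set meeting every maximum clique; an *essential vertex* is one
  contained in every maximum clique, characterised by ω(G) > ω(G − v).
  Deleting the non-neighbours of essential vertices (or of a disjoint-clique
  cover) shrinks the graph while preserving every maximum clique — dramatic on
  graphs whose maximum cliques overlap heavily, which co-expression graphs
  typically are.
* **Correlation graph builder** (`ExpressionMatrix`, `correlate`,
  `threshold_graph`) — pairwise-complete Pearson weights (or two-sided
  p-values via the t transform), optional log2 transform, inclusive
  thresholding.
* **Synthetic test kit** (`generators`, `oracle`) — planted overlapping-clique
  graphs with validated ground truth, Chung–Lu expected-degree random graphs,
  the extremal multipartite family, and a brute-force oracle, so every
  algorithm is testable without downloading any data.

## Worked example

The clique-sensitivity construction: a K5 on vertices 1–5 with three
satellites 6, 7, 8, each adjacent to three core vertices.

```bash
$ cliquekit generate --family satellite --out satellite.el
$ cliquekit enumerate satellite.el --algorithm intelligent --stats
1 2 3 4 5
k=5 cliques=1 nodes=6
```

The unique maximum clique is the core, ω = 5, found in 6 search nodes.  The
essential-set reduction identifies all five core vertices as essential and
deletes the satellites, leaving exactly the K5:

```bash
$ cliquekit reduce satellite.el --method es
1 2
1 3
...
4 5
# stderr: es  k=5  essential=1 2 3 4 5  removed=3
```

Deleting the single edge {1,2} (one noisy correlation) multiplies the answer:

```bash
$ cliquekit generate --family satellite --perturbed --out noisy.el
$ cliquekit enumerate noisy.el --stats
1 3 4 5
2 3 4 5
2 3 4 7
3 4 5 8
k=4 cliques=4 nodes=9
```

Four maximum cliques of size k − 1 = 4 — the number of maximum cliques is
extremely sensitive to single-edge perturbations, which is why enumerating
all of them matters.

The same pipeline runs on expression data:

```bash
cliquekit build-graph --input expr.tsv --threshold 0.81 --out graph.el
cliquekit enumerate graph.el --algorithm intelligent --reduce es --stats
```

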