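"""Maximum clique enumeration (MCE): every clique of size omega(G).

Three strategies, all returning identical clique sets:

* **basic** — run Bron-Kerbosch maximal-clique enumeration and keep only
  the largest cliques; the benchmark everything else must beat.
* **intelligent** — first compute k = omega(G) with the Maximum Clique
  Finder, colour-reduce the graph with that k, then run the same
  backtracking with an extra cut: any node where |COMPSUB| + |CANDIDATES|
  < k cannot reach a maximum clique and returns immediately.
* **parameterized** — MCF's own in/out vertex branching, modified to keep
  a global list of the largest cliques found so far, flushed whenever a
  larger one appears.  The degree n-2 lone-non-neighbour shortcut is
  disabled here: it preserves the clique *number* but silently discards
  cliques through the removed vertex, which is fatal for enumeration.

Node counters report the search-tree size of each strategy's own
recursion (for *intelligent*, the backtracking nodes only, so it is
directly comparable with *basic* on the shared recursion skeleton).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import bron_kerbosch as bk
from .graph import CliqueCollection, Graph
from .mcf import BranchKernel, color_exclude, degree_preprocess, extract_universal, \
    find_maximum_clique, greedy_lower_bound

__all__ = [
    "EnumerationResult",
    "enumerate_maximum_basic",
    "enumerate_maximum_intelligent",
    "enumerate_maximum_parameterized",
]

COMPLETE = "complete"
HALTED = "halted"


@dataclass(frozen=True)
class EnumerationResult:
    """k = omega(G), all maximum cliques, search-node count, status."""

    k: int
    cliques: CliqueCollection
    nodes: int
    status: str
    algorithm: str

    @property
    def complete(self) -> bool:
        return self.status == COMPLETE


def _empty(algorithm: str) -> EnumerationResult:
    return EnumerationResult(0, CliqueCollection(uniform_size=0), 0, COMPLETE, algorithm)


def enumerate_maximum_basic(G: Graph, node_budget: int | None = None) -> EnumerationResult:
    """Filter the full maximal-clique listing down to the largest cliques."""
    if G.n == 0:
        return _empty("basic")
    run = bk.enumerate_maximal(G, node_budget=node_budget)
    largest = run.cliques.largest()
    return EnumerationResult(
        largest.max_size(), largest, run.nodes,
        COMPLETE if run.complete else HALTED, "basic",
    )


def enumerate_maximum_intelligent(G: Graph, node_budget: int | None = None) -> EnumerationResult:
    """Backtracking with the precomputed-k cut, after colour preprocessing."""
    if G.n == 0:
        return _empty("intelligent")
    _, k, _ = find_maximum_clique(G)
    H, _ = color_exclude(G, k)
    run = bk.enumerate_maximal(H, k_bound=k, node_budget=node_budget)
    # the k-cut admits only maximal cliques of size >= k, and none exceed omega
    largest = CliqueCollection((c for c in run.cliques if len(c) == k), uniform_size=k)
    return EnumerationResult(
        k, largest, run.nodes, COMPLETE if run.complete else HALTED, "intelligent",
    )


def enumerate_maximum_parameterized(G: Graph, node_budget: int | None = None) -> EnumerationResult:
    """MCF branching with a flush-on-larger global list of maximum cliques."""
    if G.n == 0:
        return _empty("parameterized")

    k0 = len(greedy_lower_bound(G))
    H, _ = degree_preprocess(G, max(k0, 1))
    H, ulog = extract_universal(H)
    forced = frozenset(ulog.forced)

    kernel = BranchKernel(H.adj, "all", k0 - len(forced), frozenset(),
                          node_budget=node_budget)
    kernel.run(set(range(H.n)))

    cliques = [H.labels(c) | forced for c in kernel.found]
    if not cliques and forced:
        cliques = [frozenset(forced)]  # graph reduced to universal vertices only
    k = max((len(c) for c in cliques), default=0)
    status = COMPLETE if not kernel.halted else HALTED
    return EnumerationResult(
        k, CliqueCollection(cliques, uniform_size=k if cliques else None),
        kernel.nodes, status, "parameterized",
    )
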