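"""Bron-Kerbosch backtracking enumeration of all maximal cliques.

This is the improved (pivoting) variant of the classic recursion over the
three sets COMPSUB (current clique), CANDIDATES (vertices that can extend
it) and NOT (already-explored vertices, kept to suppress duplicates).  A
branch dies early whenever some vertex of NOT is adjacent to every
candidate — realised here by pivoting: a vertex of CANDIDATES ∪ NOT with
the most neighbours among CANDIDATES is fixed, and only candidates outside
its neighbourhood are branched on.  Ties break on the lowest internal
index, so node counts are deterministic for a fixed graph.

Cliques are streamed to a consumer as they are found; nothing is retained
unless the caller collects, since writing the cliques out typically
dominates the cost of enumerating them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .graph import CliqueCollection, Graph

__all__ = ["SearchState", "BKResult", "extend", "enumerate_maximal"]


@dataclass
class SearchState:
    """The COMPSUB / CANDIDATES / NOT triple of one recursion node."""

    compsub: list = field(default_factory=list)
    candidates: set = field(default_factory=set)
    not_set: set = field(default_factory=set)
    node_counter: int = 0


@dataclass(frozen=True)
class BKResult:
    cliques: Optional[CliqueCollection]
    nodes: int
    complete: bool


class _Recursion:
    __slots__ = ("adj", "emit", "k_bound", "limit", "nodes", "halted")

    def __init__(self, adj, emit, k_bound, limit):
        self.adj = adj
        self.emit = emit
        self.k_bound = k_bound
        self.limit = limit
        self.nodes = 0
        self.halted = False

    def extend(self, compsub: list[int], cand: set[int], nots: set[int]) -> None:
        self.nodes += 1
        if self.limit is not None and self.nodes > self.limit:
            self.halted = True
            return
        if self.k_bound is not None and len(compsub) + len(cand) < self.k_bound:
            return
        if not cand:
            if not nots:
                self.emit(frozenset(compsub))
            return
        adj = self.adj
        # pivot: most candidate-neighbours among CANDIDATES ∪ NOT, lowest index first
        pivot = -1
        best = -1
        for u in sorted(cand | nots):
            score = len(adj[u] & cand)
            if score > best:
                best = score
                pivot = u
        moved: list[int] = []
        for v in sorted(cand - adj[pivot]):
            if self.halted:
                break
            cand.remove(v)
            moved.append(v)
            compsub.append(v)
            self.extend(compsub, cand & adj[v], nots & adj[v])
            compsub.pop()
            nots.add(v)
        # restore the caller's view of CANDIDATES and NOT
        nots.difference_update(moved)
        cand.update(moved)


def extend(
    G: Graph,
    state: SearchState,
    emit: Callable[[frozenset], None],
    k_bound: int | None = None,
    node_budget: int | None = None,
) -> bool:
    """Run one Bron-Kerbosch subtree from an explicit state (label level).

    Emits every maximal clique extending ``state.compsub`` that uses only
    ``state.candidates``; the state's candidate/NOT sets are restored on
    return and ``node_counter`` is advanced.  Returns True when the subtree
    completed (no budget exhaustion).
    """
    rec = _Recursion(G.adj, lambda idxs: emit(G.labels(idxs)), k_bound, node_budget)
    compsub = [G.index(v) for v in state.compsub]
    cand = {G.index(v) for v in state.candidates}
    nots = {G.index(v) for v in state.not_set}
    rec.extend(compsub, cand, nots)
    state.candidates = G.labels(cand)
    state.not_set = G.labels(nots)
    state.node_counter += rec.nodes
    return not rec.halted


def enumerate_maximal(
    G: Graph,
    emit: Callable[[frozenset], None] | None = None,
    k_bound: int | None = None,
    node_budget: int | None = None,
) -> BKResult:
    """Enumerate all maximal cliques of G, each exactly once.

    With ``emit`` the cliques are streamed (as frozensets of labels) and
    ``cliques`` in the result is None; otherwise they are collected into a
    canonical :class:`CliqueCollection`.  ``k_bound`` prunes subtrees that
    cannot reach a clique of that size; ``node_budget`` caps the number of
    recursive calls (result.complete is False when it is hit).
    """
    collected: list[frozenset] | None = None
    if emit is None:
        collected = []
        sink = lambda idxs: collected.append(G.labels(idxs))  # noqa: E731
    else:
        sink = lambda idxs: emit(G.labels(idxs))  # noqa: E731
    if G.n == 0:
        return BKResult(CliqueCollection() if collected is not None else None, 0, True)
    rec = _Recursion(G.adj, sink, k_bound, node_budget)
    rec.extend([], set(range(G.n)), set())
    cliques = CliqueCollection(collected) if collected is not None else None
    return BKResult(cliques, rec.nodes, not rec.halted)
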