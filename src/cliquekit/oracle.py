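"""Brute-force clique oracles for small graphs.

The oracle grows cliques breadth-first, level by level: all cliques of size
s are extended to size s + 1 by appending a higher-indexed common
neighbour, and a clique is recorded as maximal exactly when it has no
common neighbour at all.  This is deliberately a different algorithm family
from the depth-first backtracking kernels it is used to verify, so the two
can disagree only through a genuine bug.  Guarded to n <= 25.
"""

from __future__ import annotations

from .graph import CliqueCollection, Graph

__all__ = ["brute_force_maximal", "brute_force_maximum", "ORACLE_MAX_N"]

ORACLE_MAX_N = 25


def brute_force_maximal(G: Graph) -> CliqueCollection:
    """All maximal cliques of G by exhaustive level-wise growth (n <= 25)."""
    if G.n > ORACLE_MAX_N:
        raise ValueError(f"brute-force oracle guarded to n <= {ORACLE_MAX_N}, got n={G.n}")
    adj = G.adj
    maximal: list[tuple[int, ...]] = []
    level: list[tuple[tuple[int, ...], frozenset[int]]] = [
        ((v,), adj[v]) for v in range(G.n)
    ]
    while level:
        nxt = []
        for clique, common in level:
            if not common:
                maximal.append(clique)
                continue
            last = clique[-1]
            for w in sorted(common):
                if w > last:
                    nxt.append((clique + (w,), common & adj[w]))
        level = nxt
    return CliqueCollection(G.labels(c) for c in maximal)


def brute_force_maximum(G: Graph) -> tuple[int, CliqueCollection]:
    """(omega(G), all maximum cliques) via the maximal-clique oracle."""
    maximal = brute_force_maximal(G)
    largest = maximal.largest()
    return largest.max_size(), largest
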