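"""Graph reductions that preserve every maximum clique.

Two observations about real co-expression graphs drive this module: their
maximum cliques overlap heavily, and very often a single clique already
intersects all of them.

* A **maximum clique cover** (MCC) is a vertex set V' meeting every
  maximum clique.  The union of a maximal family of pairwise-disjoint
  maximum cliques is such a cover, found greedily: compute a maximum
  clique, delete its vertices, repeat until the residual clique number
  drops.  Any vertex adjacent to no cover member cannot lie in a maximum
  clique and may be removed.
* An **essential vertex** lies in every maximum clique — equivalently,
  omega(G) > omega(G minus v).  Each essential vertex lets us delete all
  of its non-neighbours.  Since essential vertices lie in every maximum
  clique, only the members of one discovered maximum clique need testing:
  k extra finder calls instead of n.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import CliqueCollection, Graph, label_sort_key
from .mcf import find_maximum_clique

__all__ = [
    "CoverReport",
    "EssentialReport",
    "mcc_cover",
    "mcc_reduce",
    "essential_set",
    "es_reduce",
]


@dataclass(frozen=True)
class CoverReport:
    """A maximum clique cover: disjoint maximum cliques and their union."""

    cover: frozenset
    disjoint_cliques: CliqueCollection
    removed: frozenset
    k: int


@dataclass(frozen=True)
class EssentialReport:
    """All essential vertices and the non-neighbours they eliminate."""

    essential: frozenset
    removed: frozenset
    k: int


def mcc_cover(G: Graph) -> CoverReport:
    """Greedy maximal family of disjoint maximum cliques (a valid MCC)."""
    if G.n == 0:
        return CoverReport(frozenset(), CliqueCollection(uniform_size=0), frozenset(), 0)
    first, k, _ = find_maximum_clique(G)
    cliques = [first]
    H = G.remove_vertices(first)
    while H.n > 0:
        clique, size, _ = find_maximum_clique(H)
        if size < k:
            break
        cliques.append(clique)
        H = H.remove_vertices(clique)
    cover = frozenset().union(*cliques)
    return CoverReport(cover, CliqueCollection(cliques, uniform_size=k), frozenset(), k)


def mcc_reduce(G: Graph) -> tuple[Graph, CoverReport]:
    """Drop every vertex neither in the MCC nor adjacent to a cover member."""
    report = mcc_cover(G)
    cover = report.cover
    removed = frozenset(
        v for v in G.vertices
        if v not in cover and not (G.neighbors(v) & cover)
    )
    reduced = G.remove_vertices(removed)
    return reduced, CoverReport(cover, report.disjoint_cliques, removed, report.k)


def essential_set(G: Graph) -> EssentialReport:
    """All vertices v with omega(G) > omega(G minus v).

    Only members of one maximum clique are tested — an essential vertex
    lies in every maximum clique, hence in the one MCF just found.
    """
    if G.n == 0:
        return EssentialReport(frozenset(), frozenset(), 0)
    witness, k, _ = find_maximum_clique(G)
    essential = set()
    for v in sorted(witness, key=label_sort_key):
        _, k_without, _ = find_maximum_clique(G.remove_vertex(v))
        if k_without < k:
            essential.add(v)
    removed: set = set()
    for v in essential:
        removed.update(set(G.vertices) - set(G.neighbors(v)) - {v})
    removed -= essential  # essential vertices are mutually adjacent anyway
    return EssentialReport(frozenset(essential), frozenset(removed), k)


def es_reduce(G: Graph, fixed_point: bool = False) -> tuple[Graph, EssentialReport]:
    """Remove all non-neighbours of every essential vertex.

    One pass already preserves every maximum clique (each contains all
    essential vertices, so none of its members is a non-neighbour of one);
    ``fixed_point=True`` re-runs until no further vertex falls, purely as
    an optimisation.
    """
    report = essential_set(G)
    H = G.remove_vertices(report.removed)
    if not fixed_point:
        return H, report
    removed_total = set(report.removed)
    while report.removed:
        report = essential_set(H)
        H = H.remove_vertices(report.removed)
        removed_total |= report.removed
    return H, EssentialReport(report.essential, frozenset(removed_total), report.k)
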