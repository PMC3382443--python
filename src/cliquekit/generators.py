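"""Synthetic graph families for exercising every clique algorithm.

Real co-expression graphs have one dense, heavily overlapping region
holding most or all maximum cliques; degree-matched random graphs do not.
This module generates both regimes (plus the classical worst case and a
small hand-built sensitivity example) so the whole stack is testable
without any expression data.  All generators are bit-reproducible for a
fixed seed; labels are strings ("1", "2", ...) throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .enumeration import enumerate_maximum_basic
from .graph import CliqueCollection, Graph, GraphError
from .oracle import ORACLE_MAX_N, brute_force_maximum

__all__ = [
    "PlantedSpec",
    "GeneratorError",
    "moon_moser",
    "satellite_graph",
    "planted_overlap",
    "degree_weighted_random",
    "power_law_degrees",
    "gnp_random",
]


class GeneratorError(RuntimeError):
    """A generator could not produce a graph meeting its guarantee."""


def moon_moser(q: int) -> Graph:
    """Complete q-partite graph with parts of size 3 (n = 3q).

    The extremal family for maximal-clique count: its maximal cliques are
    exactly the 3^q = 3^(n/3) transversals picking one vertex per part.
    """
    if q < 1:
        raise GraphError("moon_moser requires q >= 1")
    labels = [str(i) for i in range(1, 3 * q + 1)]
    edges = [
        (labels[i], labels[j])
        for i in range(3 * q)
        for j in range(i + 1, 3 * q)
        if i // 3 != j // 3
    ]
    return Graph(labels, edges)


def satellite_graph(perturbed: bool = False) -> Graph:
    """K5 on {1..5} plus satellites 6~{1,2,3}, 7~{2,3,4}, 8~{3,4,5}.

    The clique-sensitivity example: unperturbed, the unique maximum clique
    is {1..5} (size 5) with each satellite reaching only 3 of its members.
    ``perturbed=True`` deletes the single edge {1,2}, after which the
    maximum cliques have size 4 — one noisy edge multiplies the answer set.
    """
    core = [str(i) for i in range(1, 6)]
    edges = list(itertools.combinations(core, 2))
    attach = {"6": ("1", "2", "3"), "7": ("2", "3", "4"), "8": ("3", "4", "5")}
    for sat, anchors in attach.items():
        edges.extend((sat, a) for a in anchors)
    if perturbed:
        edges.remove(("1", "2"))
    return Graph(core + list(attach), edges)


@dataclass(frozen=True)
class PlantedSpec:
    """Specification of an overlapping planted-clique graph.

    ``num_cliques`` cliques of ``clique_size`` vertices share exactly a
    common core of ``core_size`` vertices (private parts disjoint); every
    other vertex pair receives a background edge independently with
    probability ``background_p``.
    """

    n: int
    clique_size: int
    num_cliques: int
    core_size: int
    background_p: float
    seed: int

    def __post_init__(self):
        if not (0 <= self.core_size < self.clique_size <= self.n):
            raise GraphError("need 0 <= core_size < clique_size <= n")
        if self.num_cliques < 1:
            raise GraphError("num_cliques must be >= 1")
        if not (0.0 <= self.background_p < 1.0):
            raise GraphError("background_p must lie in [0, 1)")
        used = self.core_size + self.num_cliques * (self.clique_size - self.core_size)
        if used > self.n:
            raise GraphError(f"planted cliques need {used} vertices but n={self.n}")


def planted_overlap(
    spec: PlantedSpec, max_retries: int = 50
) -> tuple[Graph, CliqueCollection]:
    """Graph whose maximum cliques are exactly the planted, core-sharing ones.

    Background edges are rejection-sampled: after each draw the maximum
    cliques are recomputed (brute force up to n=24, Bron-Kerbosch above)
    and the draw is redone with a fresh substream if any background clique
    ties or beats the planted ones.
    """
    labels = [str(i) for i in range(1, spec.n + 1)]
    core = labels[: spec.core_size]
    private = spec.clique_size - spec.core_size
    planted = []
    pos = spec.core_size
    for _ in range(spec.num_cliques):
        planted.append(frozenset(core + labels[pos : pos + private]))
        pos += private
    planted_coll = CliqueCollection(planted, uniform_size=spec.clique_size)

    planted_edges = set()
    for clique in planted:
        planted_edges.update(
            frozenset(p) for p in itertools.combinations(sorted(clique), 2)
        )
    free_pairs = [
        (u, v)
        for u, v in itertools.combinations(labels, 2)
        if frozenset((u, v)) not in planted_edges
    ]

    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        keep = rng.random(len(free_pairs)) < spec.background_p
        edges = [tuple(sorted(p)) for p in planted_edges]
        edges += [pair for pair, k in zip(free_pairs, keep) if k]
        G = Graph(labels, edges)
        if spec.n <= ORACLE_MAX_N - 1:
            _, maximum = brute_force_maximum(G)
        else:
            maximum = enumerate_maximum_basic(G).cliques
        if maximum.as_set() == planted_coll.as_set():
            return G, planted_coll
    raise GeneratorError(
        f"planted cliques not maximum after {max_retries} draws; "
        "lower background_p"
    )


def degree_weighted_random(degrees, seed: int) -> Graph:
    """Expected-degree (Chung-Lu) random graph.

    Pair (u, v) receives an edge independently with probability
    d_u * d_v / sum(d), capped at 1.  Requires non-negative degrees with
    max(d)^2 <= sum(d) so the probabilities are valid.
    """
    d = np.asarray(list(degrees), dtype=float)
    if d.size and d.min() < 0:
        raise GraphError("degrees must be non-negative")
    total = d.sum()
    if d.size and total > 0 and d.max() ** 2 > total:
        raise GraphError("need max(degree)^2 <= sum(degrees) for valid probabilities")
    n = d.size
    labels = [str(i) for i in range(1, n + 1)]
    if n < 2 or total == 0:
        return Graph(labels, [])
    iu, ju = np.triu_indices(n, k=1)
    probs = np.minimum(d[iu] * d[ju] / total, 1.0)
    rng = np.random.default_rng(seed)
    hit = rng.random(probs.size) < probs
    edges = [(labels[i], labels[j]) for i, j in zip(iu[hit], ju[hit])]
    return Graph(labels, edges)


def power_law_degrees(
    n: int, exponent: float = 2.5, d_min: int = 1, d_max: int = 50, seed: int = 0
) -> np.ndarray:
    """Degree sequence sampled from P(d) ∝ d^-exponent on [d_min, d_max].

    The largest sampled degrees are clipped down until
    max(d)^2 <= sum(d), so the result is always a valid input for
    :func:`degree_weighted_random`.
    """
    if n < 1 or d_min < 1 or d_max < d_min:
        raise GraphError("invalid power-law parameters")
    support = np.arange(d_min, d_max + 1, dtype=float)
    weights = support ** (-exponent)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    d = rng.choice(support, size=n, p=weights)
    while d.max() ** 2 > d.sum():
        d[d == d.max()] = d.max() - 1
    return d.astype(int)


def gnp_random(n: int, p: float, seed: int) -> Graph:
    """Erdos-Renyi G(n, p) with string labels, seeded and reproducible."""
    if n < 0 or not (0.0 <= p <= 1.0):
        raise GraphError("invalid G(n, p) parameters")
    labels = [str(i) for i in range(1, n + 1)]
    if n < 2:
        return Graph(labels, [])
    iu, ju = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    hit = rng.random(iu.size) < p
    edges = [(labels[i], labels[j]) for i, j in zip(iu[hit], ju[hit])]
    return Graph(labels, edges)
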