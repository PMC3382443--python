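"""Shared fixtures: small named graphs with hand-checkable clique structure."""

import pytest

from cliquekit import Graph, gnp_random


@pytest.fixture
def k3():
    return Graph(edges=[("1", "2"), ("1", "3"), ("2", "3")])


@pytest.fixture
def k4():
    labs = ["1", "2", "3", "4"]
    return Graph(edges=[(a, b) for i, a in enumerate(labs) for b in labs[i + 1 :]])


@pytest.fixture
def k5():
    labs = ["1", "2", "3", "4", "5"]
    return Graph(edges=[(a, b) for i, a in enumerate(labs) for b in labs[i + 1 :]])


@pytest.fixture
def path3():
    return Graph(edges=[("1", "2"), ("2", "3")])


@pytest.fixture
def star4():
    """K1,3: center c, leaves l1..l3."""
    return Graph(edges=[("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def shared_edge_triangles():
    """Two triangles {a,b,c} and {a,b,d} sharing the edge {a,b}."""
    return Graph(edges=[("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d")])


@pytest.fixture
def disjoint_triangles():
    return Graph(
        edges=[("1", "2"), ("1", "3"), ("2", "3"), ("4", "5"), ("4", "6"), ("5", "6")]
    )


@pytest.fixture
def four_cycle():
    """C4: every vertex has degree 2 = n - 2; four maximum cliques (edges)."""
    return Graph(edges=[("1", "2"), ("2", "3"), ("3", "4"), ("4", "1")])


def small_suite(count: int):
    """Deterministic G(n, p) suite cycling n in {12,16,20}, p in {.3,.5,.7}."""
    combos = [(n, p) for n in (12, 16, 20) for p in (0.3, 0.5, 0.7)]
    for i in range(count):
        n, p = combos[i % len(combos)]
        yield gnp_random(n, p, seed=1000 + i)
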