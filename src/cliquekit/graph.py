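"""Simple undirected graphs shared by every clique algorithm.

Vertex labels are opaque, totally ordered identifiers (probe ids in
practice, hence usually strings).  Internally every vertex is mapped to a
dense 0-based index and adjacency is stored as one frozenset of indices per
vertex, so membership tests are O(1) and neighbourhood intersections run in
time linear in the smaller operand — the two operations that dominate both
backtracking kernels.  All iteration over vertices and neighbours follows
ascending internal index order, which makes every algorithm in the package
deterministic.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Iterator
from pathlib import Path
from typing import IO, Union

__all__ = [
    "Graph",
    "CliqueCollection",
    "GraphError",
    "ParseError",
    "label_sort_key",
    "read_graph",
    "write_graph",
    "write_cliques",
]


class GraphError(ValueError):
    """Domain error: invalid vertex, malformed structure, bad argument."""


class ParseError(GraphError):
    """A graph file could not be parsed; the message names the line."""


def label_sort_key(label: object) -> tuple:
    """Total order on labels: numeric labels sort numerically, then text.

    ``"2" < "10"`` under this key, which keeps DIMACS-style integer labels
    in natural order while remaining deterministic for arbitrary strings.
    """
    s = str(label)
    body = s[1:] if s.startswith("-") else s
    if body.isdigit():
        return (0, int(s), s)
    return (1, 0, s)


class Graph:
    """Finite simple undirected graph with constant-time adjacency queries.

    Parameters
    ----------
    vertices
        Iterable of vertex labels (may be empty; labels mentioned only in
        ``edges`` are added automatically).
    edges
        Iterable of ``(u, v)`` pairs.  Duplicates and reversed duplicates
        collapse to a single edge; self-loops raise :class:`GraphError`.
    """

    __slots__ = ("_labels", "_index", "_adj", "_m")

    def __init__(self, vertices: Iterable = (), edges: Iterable = ()) -> None:
        edge_list = [tuple(e) for e in edges]
        labels = set(vertices)
        for u, v in edge_list:
            labels.add(u)
            labels.add(v)
        self._labels: tuple = tuple(sorted(labels, key=label_sort_key))
        self._index = {lab: i for i, lab in enumerate(self._labels)}
        adj: list[set[int]] = [set() for _ in self._labels]
        m = 0
        for u, v in edge_list:
            if u == v:
                raise GraphError(f"self-loop on vertex {u!r}")
            ui, vi = self._index[u], self._index[v]
            if vi not in adj[ui]:
                adj[ui].add(vi)
                adj[vi].add(ui)
                m += 1
        self._adj: tuple[frozenset[int], ...] = tuple(frozenset(a) for a in adj)
        self._m = m

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self._labels)

    @property
    def m(self) -> int:
        return self._m

    @property
    def vertices(self) -> tuple:
        """All vertex labels in ascending internal index order."""
        return self._labels

    @property
    def adj(self) -> tuple[frozenset[int], ...]:
        """Index-level adjacency, one frozenset of neighbour indices per vertex."""
        return self._adj

    def index(self, v) -> int:
        try:
            return self._index[v]
        except KeyError:
            raise GraphError(f"vertex {v!r} not in graph") from None

    def label(self, i: int):
        return self._labels[i]

    def labels(self, indices: Iterable[int]) -> frozenset:
        return frozenset(self._labels[i] for i in indices)

    def __contains__(self, v) -> bool:
        return v in self._index

    def degree(self, v) -> int:
        return len(self._adj[self.index(v)])

    def neighbors(self, v) -> frozenset:
        return self.labels(self._adj[self.index(v)])

    def has_edge(self, u, v) -> bool:
        return self.index(v) in self._adj[self.index(u)]

    def edges(self) -> Iterator[tuple]:
        """Edges as label pairs, each once, in ascending index order."""
        for i, nbrs in enumerate(self._adj):
            for j in sorted(nbrs):
                if j > i:
                    yield (self._labels[i], self._labels[j])

    # -- derived graphs (value semantics) ----------------------------------

    def remove_vertex(self, v) -> "Graph":
        """G minus one vertex and its incident edges; self is unchanged."""
        self.index(v)  # domain check
        return self.subgraph(lab for lab in self._labels if lab != v)

    def remove_vertices(self, drop: Iterable) -> "Graph":
        drop_set = set(drop)
        for v in drop_set:
            self.index(v)
        return self.subgraph(lab for lab in self._labels if lab not in drop_set)

    def subgraph(self, keep: Iterable) -> "Graph":
        """Induced subgraph on the given labels."""
        keep_set = set(keep)
        idx = [self.index(v) for v in keep_set]
        keep_idx = set(idx)
        edges = []
        for i in idx:
            for j in self._adj[i]:
                if j in keep_idx and j > i:
                    edges.append((self._labels[i], self._labels[j]))
        return Graph(keep_set, edges)

    def is_clique(self, members: Iterable) -> bool:
        """True iff every pair of ``members`` is adjacent (vacuously for |S| <= 1)."""
        idx = sorted(self.index(v) for v in set(members))
        for a, i in enumerate(idx):
            for j in idx[a + 1 :]:
                if j not in self._adj[i]:
                    return False
        return True

    # -- equality / debugging ----------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._labels == other._labels and self._adj == other._adj

    def __hash__(self):  # graphs are de-facto immutable
        return hash((self._labels, self._adj))

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, m={self.m})"

    def check_invariants(self) -> None:
        """Assert symmetry, no self-loops and the edge-count identity."""
        total = 0
        for i, nbrs in enumerate(self._adj):
            assert i not in nbrs, "self-loop"
            total += len(nbrs)
            for j in nbrs:
                assert i in self._adj[j], "asymmetric adjacency"
        assert total == 2 * self._m, "edge count mismatch"


def _clique_sort_key(members: frozenset) -> tuple:
    return tuple(label_sort_key(v) for v in sorted(members, key=label_sort_key))


class CliqueCollection:
    """Canonical, duplicate-free set of cliques.

    Cliques are stored as frozensets of labels and iterated in canonical
    order: lexicographically by their sorted member labels.  When
    ``uniform_size`` is given, every clique must have that cardinality.
    """

    __slots__ = ("_cliques", "_uniform_size")

    def __init__(self, cliques: Iterable[Iterable] = (), uniform_size: int | None = None):
        unique = {frozenset(c) for c in cliques}
        if uniform_size is not None:
            for c in unique:
                if len(c) != uniform_size:
                    raise GraphError(
                        f"clique {sorted(map(str, c))} has size {len(c)}, "
                        f"expected uniform size {uniform_size}"
                    )
        self._cliques: tuple[frozenset, ...] = tuple(sorted(unique, key=_clique_sort_key))
        self._uniform_size = uniform_size

    @property
    def uniform_size(self) -> int | None:
        return self._uniform_size

    def __len__(self) -> int:
        return len(self._cliques)

    def __iter__(self) -> Iterator[frozenset]:
        return iter(self._cliques)

    def __contains__(self, members) -> bool:
        return frozenset(members) in set(self._cliques)

    def __getitem__(self, i: int) -> frozenset:
        return self._cliques[i]

    def as_set(self) -> frozenset:
        return frozenset(self._cliques)

    def max_size(self) -> int:
        return max((len(c) for c in self._cliques), default=0)

    def largest(self) -> "CliqueCollection":
        """Sub-collection of the largest cliques, with uniform_size set."""
        k = self.max_size()
        return CliqueCollection((c for c in self._cliques if len(c) == k), uniform_size=k)

    def __eq__(self, other) -> bool:
        if isinstance(other, CliqueCollection):
            return self._cliques == other._cliques
        if isinstance(other, (set, frozenset)):
            return self.as_set() == frozenset(frozenset(c) for c in other)
        return NotImplemented

    def __hash__(self):
        return hash(self._cliques)

    def __repr__(self) -> str:
        return f"CliqueCollection({len(self._cliques)} cliques)"


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

Source = Union[str, Path, IO, Iterable[str]]


def _iter_lines(source: Source):
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            yield from fh
        return
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        yield from data.splitlines()
        return
    yield from source


def read_graph(source: Source, fmt: str = "edge_list") -> Graph:
    """Read a graph from a path, stream or line iterable.

    ``edge_list``: one whitespace-separated pair per line, ``#`` starts a
    comment, a single-token line declares an isolated vertex.  ``dimacs``:
    ASCII clique format (``c`` comments, ``p edge n m`` header, ``e u v``
    lines with 1-based vertices, kept as string labels).
    """
    if fmt == "edge_list":
        return _read_edge_list(source)
    if fmt == "dimacs":
        return _read_dimacs(source)
    raise GraphError(f"unknown graph format {fmt!r}")


def _read_edge_list(source: Source) -> Graph:
    vertices: set = set()
    edges: list[tuple] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) == 1:
            vertices.add(tokens[0])
        elif len(tokens) == 2:
            u, v = tokens
            if u == v:
                raise ParseError(f"line {lineno}: self-loop on vertex {u!r}")
            edges.append((u, v))
        else:
            raise ParseError(f"line {lineno}: expected one edge per line, got {line!r}")
    return Graph(vertices, edges)


def _read_dimacs(source: Source) -> Graph:
    n = None
    declared_m = None
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("c"):
            continue
        tokens = line.split()
        if tokens[0] == "p":
            if len(tokens) != 4 or tokens[1] != "edge":
                raise ParseError(f"line {lineno}: malformed problem line {line!r}")
            try:
                n, declared_m = int(tokens[2]), int(tokens[3])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer sizes in {line!r}") from None
        elif tokens[0] == "e":
            if n is None:
                raise ParseError(f"line {lineno}: edge before problem line")
            if len(tokens) != 3:
                raise ParseError(f"line {lineno}: malformed edge line {line!r}")
            try:
                u, v = int(tokens[1]), int(tokens[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer vertex in {line!r}") from None
            if not (1 <= u <= n and 1 <= v <= n):
                raise ParseError(f"line {lineno}: vertex out of range 1..{n}")
            if u == v:
                raise ParseError(f"line {lineno}: self-loop on vertex {u}")
            edges.append((str(u), str(v)))
        else:
            raise ParseError(f"line {lineno}: unrecognized line {line!r}")
    if n is None:
        raise ParseError("missing 'p edge' header")
    if declared_m != len(edges):
        raise ParseError(
            f"header declares {declared_m} edges but {len(edges)} edge lines found"
        )
    return Graph((str(i) for i in range(1, n + 1)), edges)


def _open_sink(sink):
    if isinstance(sink, (str, Path)):
        return open(sink, "wt", encoding="utf-8"), True
    return sink, False


def _write_text(sink, text: str) -> None:
    fh, close = _open_sink(sink)
    try:
        if hasattr(fh, "buffer"):
            fh.write(text)
        else:
            try:
                fh.write(text)
            except TypeError:
                fh.write(text.encode("utf-8"))
    finally:
        if close:
            fh.close()


def write_graph(G: Graph, sink, fmt: str = "edge_list") -> None:
    """Write a graph; deterministic (ascending index order) output."""
    if fmt == "edge_list":
        lines = [f"{u} {v}" for u, v in G.edges()]
        covered = {v for e in G.edges() for v in e}
        lines += [str(v) for v in G.vertices if v not in covered]
        _write_text(sink, "".join(line + "\n" for line in lines))
    elif fmt == "dimacs":
        out = [f"p edge {G.n} {G.m}"]
        for u, v in G.edges():
            out.append(f"e {G.index(u) + 1} {G.index(v) + 1}")
        _write_text(sink, "".join(line + "\n" for line in out))
    else:
        raise GraphError(f"unknown graph format {fmt!r}")


def clique_line(members: Iterable) -> str:
    return " ".join(str(v) for v in sorted(members, key=label_sort_key))


def write_cliques(cliques: CliqueCollection, sink) -> None:
    """One clique per line, members sorted by label, canonical line order.

    Bit-exact across runs: the collection's canonical ordering fixes both
    the within-line and the between-line order.
    """
    _write_text(sink, "".join(clique_line(c) + "\n" for c in cliques))
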