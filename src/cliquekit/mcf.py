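"""Maximum Clique Finder (MCF): one maximum clique and omega(G).

The finder follows the fixed-parameter playbook that mirrors vertex-cover
branching:

1. a greedy heuristic builds a reasonably large clique C, giving a lower
   bound k = |C| on the clique number;
2. preprocessing shrinks the graph — vertices of degree < k - 1 can never
   join a clique of size k ("low_degree"); vertices adjacent to everything
   must be in every maximum clique and are set aside ("universal");
   greedy-colouring each vertex's closed neighbourhood removes vertices
   whose neighbourhood admits fewer than k colours ("color");
3. recursive in/out branching on the residual graph decides, per vertex,
   whether it is in the clique or not, pruning any node whose clique plus
   candidate pool cannot beat the best clique found so far.

The same branching kernel, run in "all" mode with a non-strict bound and
without the single-witness-only degree n-2 rule, powers parameterized
maximum clique enumeration (see :mod:`cliquekit.enumeration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import Graph, GraphError

__all__ = [
    "ReductionLog",
    "greedy_lower_bound",
    "degree_preprocess",
    "extract_universal",
    "color_exclude",
    "find_maximum_clique",
]


@dataclass
class ReductionLog:
    """Audit trail of preprocessing: removals, forced vertices, bound."""

    removed: list[tuple[object, str]] = field(default_factory=list)
    forced: list = field(default_factory=list)
    lower_bound: int = 0

    def merge(self, other: "ReductionLog") -> None:
        self.removed.extend(other.removed)
        self.forced.extend(other.forced)
        self.lower_bound = max(self.lower_bound, other.lower_bound)

    def raise_bound(self, k: int) -> None:
        if k < self.lower_bound:
            raise GraphError("clique lower bound may never decrease")
        self.lower_bound = k


# ---------------------------------------------------------------------------
# Greedy lower bound
# ---------------------------------------------------------------------------

def greedy_lower_bound(G: Graph) -> frozenset:
    """Greedy clique: repeatedly add the highest-degree common neighbour.

    Starts from the highest-degree vertex and its highest-degree
    neighbour, then repeatedly picks the highest-degree vertex adjacent to
    the whole clique, discarding non-adjacent vertices each round, until
    no vertex outside the clique remains.  Degrees are taken in G; ties
    break on the lowest internal index.  On an edgeless graph the single
    lowest-index vertex is returned (degenerate case).
    """
    if G.n == 0:
        return frozenset()
    adj = G.adj
    deg = [len(a) for a in adj]
    if G.m == 0:
        return frozenset({G.label(0)})

    def best_of(pool) -> int:
        return max(sorted(pool), key=lambda v: deg[v])

    v = best_of(range(G.n))
    w = best_of(adj[v])
    clique = {v, w}
    pool = set(adj[v]) & adj[w]
    while pool:
        u = best_of(pool)
        clique.add(u)
        pool &= adj[u]
    return G.labels(clique)


# ---------------------------------------------------------------------------
# Preprocessing rules
# ---------------------------------------------------------------------------

def degree_preprocess(G: Graph, k: int) -> tuple[Graph, ReductionLog]:
    """Peel every vertex of degree < k - 1 to a fixed point (tag "low_degree")."""
    if k < 1:
        raise GraphError("lower bound k must be >= 1")
    log = ReductionLog(lower_bound=k)
    alive = set(range(G.n))
    deg = {v: len(G.adj[v]) for v in alive}
    queue = sorted(v for v in alive if deg[v] < k - 1)
    while queue:
        nxt: set[int] = set()
        for v in queue:
            if v not in alive:
                continue
            alive.remove(v)
            log.removed.append((G.label(v), "low_degree"))
            for u in G.adj[v]:
                if u in alive:
                    deg[u] -= 1
                    if deg[u] < k - 1:
                        nxt.add(u)
        queue = sorted(nxt)
    return G.subgraph(G.labels(alive)), log


def extract_universal(G: Graph) -> tuple[Graph, ReductionLog]:
    """Move vertices adjacent to all others to the forced list, repeatedly.

    A universal vertex lies in every maximal (hence every maximum) clique,
    so it can be set aside and re-attached to whatever clique the search
    finds in the residual graph.
    """
    log = ReductionLog()
    H = G
    while H.n > 0:
        hit = None
        for i in range(H.n):
            if len(H.adj[i]) == H.n - 1:
                hit = H.label(i)
                break
        if hit is None:
            break
        log.forced.append(hit)
        H = H.remove_vertex(hit)
    return H, log


def _greedy_color_count(members: set[int], adj) -> int:
    """First-fit colouring of the induced subgraph, largest degree first."""
    order = sorted(members, key=lambda v: (-len(adj[v] & members), v))
    color: dict[int, int] = {}
    used = 0
    for v in order:
        taken = {color[u] for u in adj[v] & members if u in color}
        c = 0
        while c in taken:
            c += 1
        color[v] = c
        used = max(used, c + 1)
    return used


def color_exclude(G: Graph, k: int) -> tuple[Graph, ReductionLog]:
    """Remove vertices whose closed neighbourhood colours with < k colours.

    If v and its neighbours can be greedy-coloured with fewer than k
    colours, no clique of size k can contain v (a k-clique forces k
    colours), so v is dropped (tag "color").  Passes repeat until one
    removes nothing.
    """
    if k < 1:
        raise GraphError("lower bound k must be >= 1")
    log = ReductionLog(lower_bound=k)
    alive = set(range(G.n))
    adj = G.adj
    changed = True
    while changed:
        changed = False
        for v in sorted(alive):
            closed = (adj[v] & alive) | {v}
            if _greedy_color_count(closed, adj) < k:
                alive.remove(v)
                log.removed.append((G.label(v), "color"))
                changed = True
    return G.subgraph(G.labels(alive)), log


# ---------------------------------------------------------------------------
# Branching kernel (shared by MCF and parameterized enumeration)
# ---------------------------------------------------------------------------

class BranchKernel:
    """In/out vertex branching with interleaved reductions.

    mode="single": find one maximum clique; prunes with a strict bound and
    may apply the degree n-2 rule (a candidate with a lone non-neighbour
    lets us discard that non-neighbour, since any clique through the
    non-neighbour can be remapped through the candidate at equal size) —
    sound only when a single witness is wanted.

    mode="all": enumerate every maximum clique; the bound admits ties so
    equal-size cliques survive, the n-2 rule is disabled, and a global
    list of largest-so-far cliques is flushed whenever a larger one
    appears.
    """

    def __init__(self, adj, mode: str, best_size: int, witness: frozenset[int],
                 node_budget: int | None = None):
        if mode not in ("single", "all"):
            raise GraphError(f"unknown kernel mode {mode!r}")
        self.adj = adj
        self.all_mode = mode == "all"
        self.best = best_size
        self.witness = witness
        self.found: set[frozenset[int]] = set()
        self.limit = node_budget
        self.nodes = 0
        self.halted = False

    def run(self, candidates: set[int]) -> None:
        self._rec([], set(candidates))

    # the recursion works on (current clique, candidates = common neighbours)
    def _rec(self, cur: list[int], cand: set[int]) -> None:
        self.nodes += 1
        if self.limit is not None and self.nodes > self.limit:
            self.halted = True
            return
        adj = self.adj
        cur = list(cur)
        # interleaved reductions, to a fixed point
        while True:
            need = self.best - len(cur) + (0 if self.all_mode else 1)
            drop = [w for w in cand if len(adj[w] & cand) < need - 1]
            if drop:
                cand.difference_update(drop)
                continue
            universal = [c for c in sorted(cand) if adj[c] >= cand - {c}]
            if universal:
                cur.extend(universal)
                cand.difference_update(universal)
                continue
            if not self.all_mode:
                lone = None
                for w in sorted(cand):
                    non = cand - adj[w] - {w}
                    if len(non) == 1:
                        lone = next(iter(non))
                        break
                if lone is not None:
                    cand.remove(lone)
                    continue
            break
        if not cand:
            self._record(cur)
            return
        size = len(cur)
        if self.all_mode:
            if size + len(cand) < self.best:
                return
        else:
            if size + len(cand) <= self.best:
                return
        # branch vertex: most neighbours among candidates, lowest index tie
        v = -1
        score = -1
        for u in sorted(cand):
            s = len(adj[u] & cand)
            if s > score:
                score = s
                v = u
        self._rec(cur + [v], cand & adj[v])  # v in the clique
        if self.halted:
            return
        self._rec(cur, cand - {v})  # v out of the clique

    def _record(self, cur: list[int]) -> None:
        size = len(cur)
        if self.all_mode:
            if size > self.best:
                self.best = size
                self.found = {frozenset(cur)}  # flush on larger
            elif size == self.best:
                self.found.add(frozenset(cur))
        elif size > self.best:
            self.best = size
            self.witness = frozenset(cur)


# ---------------------------------------------------------------------------
# The finder
# ---------------------------------------------------------------------------

def find_maximum_clique(G: Graph, use_color: bool = True) -> tuple[frozenset, int, ReductionLog]:
    """Return (maximum clique, omega(G), reduction log).

    Pipeline: greedy lower bound, then low-degree peeling, universal
    extraction and (optionally, root only) colour exclusion, then in/out
    branching on the residual graph.  The greedy clique minus any forced
    vertices survives every reduction and seeds the branch bound, so the
    search only has to beat it, never rebuild it.
    """
    log = ReductionLog()
    if G.n == 0:
        return frozenset(), 0, log
    if G.m == 0:
        log.raise_bound(1)
        return frozenset({G.label(0)}), 1, log

    C0 = greedy_lower_bound(G)
    k = len(C0)
    log.raise_bound(k)

    H, dlog = degree_preprocess(G, k)
    log.merge(dlog)
    H, ulog = extract_universal(H)
    log.merge(ulog)
    forced = list(ulog.forced)
    k_res = k - len(forced)
    if use_color and k_res >= 1 and H.n > 0:
        H, clog = color_exclude(H, k_res)
        log.merge(clog)

    seed = frozenset(v for v in C0 if v not in set(forced))
    seed_idx = frozenset(H.index(v) for v in seed)
    kernel = BranchKernel(H.adj, "single", len(seed_idx), seed_idx)
    kernel.run(set(range(H.n)))

    clique = H.labels(kernel.witness) | frozenset(forced)
    log.raise_bound(len(clique))
    return clique, len(clique), log
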