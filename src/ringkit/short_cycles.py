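"""Minimum cycle basis, relevant and essential cycles, and the auxiliary
short cycle sets.

The machinery is Vismara's compact-family construction.  Vertices are
ranked (degree ascending, index ascending) and for each root ``r`` a BFS is
run in the subgraph induced by the vertices of rank <= rank(r).  Cycle
*families* are read off the BFS:

* odd family  <r, y, z>: an edge y-z with d(y) = d(z) closes a cycle of
  weight 2 d(y) + 1 through r;
* even family <r, q, y, z>: two predecessors y, z of a vertex q close a
  cycle of weight 2 d(q) through r;

in both cases subject to S(r, y) ∩ S(r, z) = {r}, where S(r, v) is the set
of vertices lying on *any* shortest r-v path.  That disjointness condition
makes every pairing of a shortest r-y path with a shortest r-z path an
elementary cycle, so a family holds exactly
``count(paths to y) × count(paths to z)`` member cycles, all of the same
weight, and the members can be counted without materialising any walks.

Every cycle of the graph is rooted at its rank-maximal vertex, so the
families collectively contain every relevant cycle.  In a fused or bridged
(non-simple) biconnected component every cycle passes through a vertex of
degree > 2, and such vertices rank above all degree-2 vertices — hence only
searches rooted at degree > 2 vertices can yield families, and the
restricted mode skips the rest (e.g. 2 searches for naphthalene, 4 for
anthracene, instead of one per vertex).

A family is *relevant* (all members belong to some minimum cycle basis) iff
its prototype is not a GF(2) sum of strictly shorter cycles, tested by
Gaussian elimination against the span of the smaller-weight prototypes.  A
minimum cycle basis falls out of a greedy pass over prototypes in weight
order; the essential cycles (intersection of all MCBs) are the relevant
single-member families whose prototype is independent of all *other*
relevant prototypes of weight <= its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .graph_core import (
    Cycle,
    CycleSetResult,
    EdgeBitSet,
    MolGraph,
    RelevantCountError,
    circuit_rank,
)

__all__ = [
    "CycleFamily",
    "CycleBasis",
    "InitialCycles",
    "initial_cycles",
    "minimum_cycle_basis",
    "relevant_cycles",
    "essential_cycles",
    "count_relevant",
    "vertex_short_cycles",
    "edge_short_cycles",
    "triplet_cycles",
    "DEFAULT_RELEVANT_LIMIT",
]

DEFAULT_RELEVANT_LIMIT = 1_000_000


class _Gf2Space:
    """Row space over GF(2), rows keyed by pivot (highest set bit)."""

    __slots__ = ("rows",)

    def __init__(self) -> None:
        self.rows: dict[int, int] = {}

    def reduce(self, v: int) -> int:
        rows = self.rows
        while v:
            p = v.bit_length() - 1
            row = rows.get(p)
            if row is None:
                break
            v ^= row
        return v

    def contains(self, v: int) -> bool:
        return self.reduce(v) == 0

    def add(self, v: int) -> bool:
        """Insert if independent; returns True when the rank grew."""
        v = self.reduce(v)
        if v == 0:
            return False
        self.rows[v.bit_length() - 1] = v
        return True


@dataclass
class _RootSearch:
    """BFS record from one root: distances, shortest-path DAG, path counts
    and S-sets (vertex bit masks of all shortest-path vertices)."""

    root: int
    dist: list[int]
    preds: list[list[int]]
    n_paths: list[int]
    s_mask: list[int]

    def paths_to(self, v: int) -> Iterator[list[int]]:
        """All shortest root->v paths, predecessors visited in ascending
        order so enumeration is deterministic."""
        if v == self.root:
            yield [self.root]
            return
        for p in self.preds[v]:
            for head in self.paths_to(p):
                yield head + [v]

    def lex_path_to(self, v: int) -> list[int]:
        path = [v]
        while v != self.root:
            v = self.preds[v][0]
            path.append(v)
        path.reverse()
        return path


@dataclass(frozen=True)
class CycleFamily:
    """A compact family of same-weight cycles through a common root.

    ``member_count = path_count_p * path_count_q`` because the two
    shortest-path bundles share no vertex besides the root.
    """

    root: int
    weight: int
    parity: str  # "odd" (closing edge y-z) or "even" (apex q)
    y: int
    z: int
    q: Optional[int]
    prototype: Cycle
    path_count_p: int
    path_count_q: int
    path_dag: _RootSearch = field(repr=False, compare=False)

    @property
    def member_count(self) -> int:
        return self.path_count_p * self.path_count_q

    def members(self, g: MolGraph) -> Iterator[Cycle]:
        """Materialise every cycle of the family."""
        for left in self.path_dag.paths_to(self.y):
            for right in self.path_dag.paths_to(self.z):
                mid = [self.q] if self.q is not None else []
                verts = left + mid + right[::-1][:-1]
                yield Cycle.from_vertices(g, verts)


@dataclass(frozen=True)
class CycleBasis:
    """A GF(2)-independent set of cycles; complete when len == circuit rank."""

    cycles: tuple[Cycle, ...]
    edge_union: EdgeBitSet
    rank: int

    @property
    def total_weight(self) -> int:
        return sum(c.weight for c in self.cycles)

    @property
    def complete(self) -> bool:
        return len(self.cycles) == self.rank


def _vertex_ranks(g: MolGraph) -> list[int]:
    """rank[v]: position under (degree ascending, index ascending)."""
    order = sorted(range(g.n_vertices), key=lambda v: (g.degree(v), v))
    rank = [0] * g.n_vertices
    for i, v in enumerate(order):
        rank[v] = i
    return rank


def _bfs_restricted(g: MolGraph, root: int, allowed: list[bool]) -> _RootSearch:
    n = g.n_vertices
    dist = [-1] * n
    preds: list[list[int]] = [[] for _ in range(n)]
    n_paths = [0] * n
    s_mask = [0] * n
    dist[root] = 0
    n_paths[root] = 1
    s_mask[root] = 1 << root
    frontier = [root]
    order = [root]
    while frontier:
        nxt: list[int] = []
        for v in frontier:
            for w, _ in g.adjacency[v]:
                if not allowed[w]:
                    continue
                if dist[w] == -1:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
                    order.append(w)
                if dist[w] == dist[v] + 1:
                    preds[w].append(v)
        frontier = nxt
    for v in order[1:]:
        preds[v].sort()
        m = 1 << v
        c = 0
        for p in preds[v]:
            m |= s_mask[p]
            c += n_paths[p]
        s_mask[v] = m
        n_paths[v] = c
    return _RootSearch(root=root, dist=dist, preds=preds, n_paths=n_paths, s_mask=s_mask)


class InitialCycles:
    """The compact initial cycle set of a graph.

    With ``only_branch_vertices=True`` (valid inside a non-simple biconnected
    component) shortest-path searches are issued only from vertices of
    degree > 2; ``search_count`` records how many BFS runs were performed.
    Families are sorted by (weight, root, y, z, q) for determinism.
    """

    def __init__(self, graph: MolGraph, only_branch_vertices: bool = False):
        self.graph = graph
        self.only_branch_vertices = only_branch_vertices
        self.search_count = 0
        self.families: list[CycleFamily] = []
        self._compute()
        self.families.sort(
            key=lambda f: (f.weight, f.root, f.y, f.z, -1 if f.q is None else f.q)
        )

    def _compute(self) -> None:
        g = self.graph
        rank = _vertex_ranks(g)
        by_rank = sorted(range(g.n_vertices), key=lambda v: rank[v])
        allowed = [False] * g.n_vertices
        for r in by_rank:
            allowed[r] = True  # grow the prefix V_r one vertex at a time
            if self.only_branch_vertices and g.degree(r) <= 2:
                continue
            self.search_count += 1
            bfs = _bfs_restricted(g, r, allowed)
            self._families_from(bfs)

    def _families_from(self, bfs: _RootSearch) -> None:
        g = self.graph
        r = bfs.root
        root_bit = 1 << r
        dist = bfs.dist
        # odd families: non-tree edge y-z with d(y) == d(z)
        for y, z in g.edges:
            if dist[y] == -1 or dist[z] == -1 or dist[y] != dist[z]:
                continue
            if bfs.s_mask[y] & bfs.s_mask[z] != root_bit:
                continue
            if y > z:
                y, z = z, y
            proto = Cycle.from_vertices(
                g, bfs.lex_path_to(y) + bfs.lex_path_to(z)[::-1][:-1]
            )
            self.families.append(
                CycleFamily(
                    root=r,
                    weight=2 * dist[y] + 1,
                    parity="odd",
                    y=y,
                    z=z,
                    q=None,
                    prototype=proto,
                    path_count_p=bfs.n_paths[y],
                    path_count_q=bfs.n_paths[z],
                    path_dag=bfs,
                )
            )
        # even families: two predecessors y, z of an apex q
        for q in range(g.n_vertices):
            ps = bfs.preds[q]
            if len(ps) < 2:
                continue
            for i in range(len(ps)):
                for j in range(i + 1, len(ps)):
                    y, z = ps[i], ps[j]
                    if bfs.s_mask[y] & bfs.s_mask[z] != root_bit:
                        continue
                    proto = Cycle.from_vertices(
                        g,
                        bfs.lex_path_to(y) + [q] + bfs.lex_path_to(z)[::-1][:-1],
                    )
                    self.families.append(
                        CycleFamily(
                            root=r,
                            weight=2 * dist[q],
                            parity="even",
                            y=y,
                            z=z,
                            q=q,
                            prototype=proto,
                            path_count_p=bfs.n_paths[y],
                            path_count_q=bfs.n_paths[z],
                            path_dag=bfs,
                        )
                    )


def initial_cycles(component: MolGraph) -> list[CycleFamily]:
    """Initial cycle families of a non-simple biconnected component,
    searching only from degree > 2 vertices."""
    return InitialCycles(component, only_branch_vertices=True).families


# ---------------------------------------------------------------------------
# Derived sets
# ---------------------------------------------------------------------------

def _relevant_families(families: list[CycleFamily]) -> list[CycleFamily]:
    """Families whose members belong to at least one MCB.

    A prototype of weight w is relevant iff it is linearly independent of the
    span of all strictly smaller-weight prototypes (which equals the span of
    all strictly shorter cycles).  Same-weight prototypes are *not* tested
    against each other: interchangeable same-weight cycles are all relevant.
    """
    shorter = _Gf2Space()
    relevant: list[CycleFamily] = []
    i = 0
    fams = families
    while i < len(fams):
        j = i
        w = fams[i].weight
        while j < len(fams) and fams[j].weight == w:
            j += 1
        group = fams[i:j]
        for fam in group:
            if shorter.reduce(fam.prototype.edge_bits.bits) != 0:
                relevant.append(fam)
        for fam in group:
            shorter.add(fam.prototype.edge_bits.bits)
        i = j
    return relevant


def _greedy_basis(
    families: list[CycleFamily],
    rank: int,
    n_edges: int,
    use_shortcut: bool = True,
) -> CycleBasis:
    """Greedy minimum basis over prototypes in non-decreasing weight.

    ``use_shortcut`` enables the edge-union test: a candidate with an edge
    not yet covered by the basis is independent without elimination.
    """
    basis: list[Cycle] = []
    space = _Gf2Space()
    union = 0
    for fam in families:
        if len(basis) == rank:
            break  # basis complete at circuit rank
        cand = fam.prototype
        bits = cand.edge_bits.bits
        if use_shortcut and (bits & union).bit_count() < cand.weight:
            space.add(bits)
            independent = True
        else:
            independent = space.add(bits)
        if independent:
            basis.append(cand)
            union |= bits
    return CycleBasis(
        cycles=tuple(basis),
        edge_union=EdgeBitSet(n_edges, union),
        rank=rank,
    )


def minimum_cycle_basis(g: MolGraph, use_shortcut: bool = True) -> CycleBasis:
    """A minimum-weight cycle basis of the whole graph.

    The basis is non-unique in general; candidate prototypes are processed
    in a fixed deterministic order so repeated runs agree.
    """
    fams = InitialCycles(g).families
    return _greedy_basis(fams, circuit_rank(g), g.n_edges, use_shortcut)


def _relevant_of(g: MolGraph, only_branch: bool = False) -> list[CycleFamily]:
    return _relevant_families(InitialCycles(g, only_branch).families)


def count_relevant(g: MolGraph) -> int:
    """Number of relevant cycles, via path-count products — no walks built."""
    return sum(f.member_count for f in _relevant_of(g))


def _enumerate_relevant(
    g: MolGraph, rel: list[CycleFamily], limit: Optional[int]
) -> list[Cycle]:
    total = sum(f.member_count for f in rel)
    if limit is not None and total > limit:
        raise RelevantCountError(total, limit)
    seen: dict[EdgeBitSet, Cycle] = {}
    for fam in rel:
        for cyc in fam.members(g):
            seen.setdefault(cyc.edge_bits, cyc)
    return sorted(seen.values())


def relevant_cycles(
    g: MolGraph, limit: Optional[int] = DEFAULT_RELEVANT_LIMIT
) -> CycleSetResult:
    """The union of all minimum cycle bases (unique, possibly exponential).

    Raises :class:`RelevantCountError` when the member count — known before
    any walk is generated — exceeds ``limit``.
    """
    cycles = _enumerate_relevant(g, _relevant_of(g), limit)
    return CycleSetResult(method="relevant", cycles=tuple(cycles))


def _essential_from_relevant(rel: list[CycleFamily]) -> list[Cycle]:
    """Essential = intersection of all MCBs, decided on prototypes.

    Any family with several members is interchangeable within a basis, so
    only single-member families are candidates; such a cycle is essential
    iff it is independent of every *other* relevant prototype of weight not
    exceeding its own.
    """
    out: list[Cycle] = []
    for i, fam in enumerate(rel):
        if fam.member_count != 1:
            continue
        others = _Gf2Space()
        for j, other in enumerate(rel):
            if j != i and other.weight <= fam.weight:
                others.add(other.prototype.edge_bits.bits)
        if not others.contains(fam.prototype.edge_bits.bits):
            out.append(fam.prototype)
    return sorted(out)


def essential_cycles(g: MolGraph) -> CycleSetResult:
    """Cycles belonging to every minimum cycle basis (always polynomial)."""
    cycles = _essential_from_relevant(_relevant_of(g))
    return CycleSetResult(method="essential", cycles=tuple(cycles))


def _short_cycles_by(
    g: MolGraph, keys_of_cycle, method: str, limit: Optional[int]
) -> CycleSetResult:
    """Per-key minimum-weight cycles drawn from the relevant set.

    Every shortest cycle through a vertex (or edge) is relevant: a GF(2)
    decomposition into strictly shorter cycles would contain a shorter cycle
    through that vertex (edge).  So per-key minima over the relevant cycles
    are the true minima, with ties kept.  No basis check is performed.
    """
    members = _enumerate_relevant(g, _relevant_of(g), limit)
    best: dict[object, int] = {}
    for cyc in members:
        for key in keys_of_cycle(cyc):
            w = best.get(key)
            if w is None or cyc.weight < w:
                best[key] = cyc.weight
    chosen: dict[EdgeBitSet, Cycle] = {}
    for cyc in members:
        for key in keys_of_cycle(cyc):
            if best[key] == cyc.weight:
                chosen.setdefault(cyc.edge_bits, cyc)
    return CycleSetResult(method=method, cycles=tuple(sorted(chosen.values())))


def vertex_short_cycles(
    g: MolGraph, limit: Optional[int] = DEFAULT_RELEVANT_LIMIT
) -> CycleSetResult:
    """All shortest cycles through each cyclic vertex, deduplicated."""
    return _short_cycles_by(g, lambda c: c.vertices(), "vertex_short", limit)


def edge_short_cycles(
    g: MolGraph, limit: Optional[int] = DEFAULT_RELEVANT_LIMIT
) -> CycleSetResult:
    """All shortest cycles through each cyclic edge (the LSSR set)."""
    return _short_cycles_by(
        g, lambda c: c.edge_bits.indices(), "edge_short", limit
    )


def triplet_cycles(g: MolGraph, unique: bool = True) -> CycleSetResult:
    """Shortest cycle through each length-2 path u-v-w of the cyclic subgraph.

    The triple is realised as a middle vertex v with a neighbour pair
    {u, w}; the cycle is u-v-w closed by a shortest u-w path avoiding v.
    Captures envelope rings (naphthalene's 10-cycle) while avoiding the
    largest fused perimeters.  ``unique`` deduplicates by edge set; the
    non-unique set keeps one cycle per triple.
    """
    from .ring_search import ring_search

    part = ring_search(g)
    cyc_edges = part.cyclic_edges
    cycles: list[Cycle] = []
    for v in sorted(part.cyclic_vertices):
        nbrs = sorted(
            w for w, ei in g.adjacency[v] if ei in cyc_edges
        )
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                u, w = nbrs[i], nbrs[j]
                path = _shortest_path_avoiding(g, u, w, v, cyc_edges)
                if path is None:
                    continue
                cycles.append(Cycle.from_vertices(g, [v] + path))
    if unique:
        seen: dict[EdgeBitSet, Cycle] = {}
        for c in cycles:
            seen.setdefault(c.edge_bits, c)
        cycles = sorted(seen.values())
    return CycleSetResult(method="triplet", cycles=tuple(cycles))


def _shortest_path_avoiding(
    g: MolGraph, src: int, dst: int, avoid: int, edge_mask: EdgeBitSet
) -> Optional[list[int]]:
    """Lexicographically smallest shortest src->dst path in the cyclic
    subgraph with ``avoid`` removed; None if disconnected."""
    dist = {src: 0}
    pred: dict[int, int] = {}
    frontier = [src]
    while frontier and dst not in dist:
        nxt = []
        for x in sorted(frontier):
            for y, ei in g.adjacency[x]:
                if y == avoid or ei not in edge_mask or y in dist:
                    continue
                dist[y] = dist[x] + 1
                pred[y] = x
                nxt.append(y)
        frontier = nxt
    if dst not in dist:
        return None
    path = [dst]
    while path[-1] != src:
        path.append(pred[path[-1]])
    path.reverse()
    return path
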