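"""All elementary cycles by path-graph reduction with a degree threshold.

Vertices are removed one at a time in a predetermined order (degree
ascending, index ascending — fixed before reduction starts and never
revised).  The path graph starts as the input graph; removing a vertex x
joins every pair of paths meeting at x whose vertex sets share only x, and
a join whose far endpoints coincide emits an elementary cycle.  Because the
removal order is predetermined, each path edge needs to be indexed only at
whichever endpoint is removed first (directed indexing), so edges are
deleted in bulk exactly once, when their index vertex is reduced.

Interiors are vertex bit sets; the joinability test is a bit intersection.

Feasibility is machine independent: if any path-graph vertex degree would
exceed ``max_degree`` (default 684; values up to 5000 were the tested
range) the run aborts with a deterministic :class:`FeasibilityError`
identifying the vertex — the same input and threshold always fail
identically, unlike a wall-clock timeout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .graph_core import (
    ComponentInfo,
    Cycle,
    CycleSetResult,
    EdgeBitSet,
    FeasibilityError,
    Feasibility,
    MolGraph,
)

__all__ = [
    "DEFAULT_MAX_DEGREE",
    "MAX_TESTED_DEGREE",
    "PathEdge",
    "removal_order",
    "path_graph_cycles",
    "all_cycles",
]

DEFAULT_MAX_DEGREE = 684
MAX_TESTED_DEGREE = 5000


@dataclass(frozen=True)
class PathEdge:
    """A reduced path between two endpoints.

    ``interior`` is a vertex bit mask of the vertices strictly between the
    endpoints; ``walk`` runs from ``a`` to ``b``.
    """

    a: int
    b: int
    interior: int
    walk: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.walk) - 1


def removal_order(g: MolGraph) -> list[int]:
    """Predetermined reduction order: degree ascending, index ascending."""
    return sorted(range(g.n_vertices), key=lambda v: (g.degree(v), v))


def path_graph_cycles(g: MolGraph, max_degree: int = DEFAULT_MAX_DEGREE) -> list[Cycle]:
    """Every elementary cycle of the graph, deduplicated by edge set.

    Raises :class:`FeasibilityError` when the evolving path graph's degree
    bound is exceeded (checked after each join).
    """
    order = removal_order(g)
    pos = [0] * g.n_vertices
    for i, v in enumerate(order):
        pos[v] = i
    # edges indexed at whichever endpoint is reduced first
    indexed: list[list[PathEdge]] = [[] for _ in range(g.n_vertices)]
    degree = [0] * g.n_vertices
    for u, v in g.edges:
        x, y = (u, v) if pos[u] < pos[v] else (v, u)
        indexed[x].append(PathEdge(a=x, b=y, interior=0, walk=(x, y)))
        degree[u] += 1
        degree[v] += 1
    found: dict[EdgeBitSet, Cycle] = {}
    for x in order:
        incident = indexed[x]
        indexed[x] = []
        for e in incident:
            degree[e.a] -= 1
            degree[e.b] -= 1
        for i in range(len(incident)):
            e1 = incident[i]
            for j in range(i + 1, len(incident)):
                e2 = incident[j]
                if e1.interior & e2.interior:
                    continue
                a, b = e1.b, e2.b
                if a == b:
                    # closed: x .. a .. x, elementary by the disjointness test
                    if (e1.interior | e2.interior) >> a & 1:
                        continue
                    cyc = Cycle.from_vertices(g, e1.walk[::-1][:-1] + e2.walk[:-1])
                    found.setdefault(cyc.edge_bits, cyc)
                    continue
                if e1.interior >> b & 1 or e2.interior >> a & 1:
                    continue
                walk = e1.walk[::-1] + e2.walk[1:]
                interior = e1.interior | e2.interior | (1 << x)
                if pos[b] < pos[a]:
                    # orient the stored walk to start at the index vertex
                    a, b = b, a
                    walk = walk[::-1]
                new = PathEdge(a=a, b=b, interior=interior, walk=walk)
                indexed[a].append(new)
                degree[a] += 1
                degree[b] += 1
                worst = a if degree[a] >= degree[b] else b
                if degree[worst] > max_degree:
                    raise FeasibilityError(worst, degree[worst], max_degree)
    return sorted(found.values())


def all_cycles(g: MolGraph, max_degree: int = DEFAULT_MAX_DEGREE) -> CycleSetResult:
    """All elementary cycles with biconnected preprocessing.

    Simple biconnected components short-circuit to their single cycle;
    non-simple components go through the path-graph reduction.  Feasibility
    errors propagate with the offending vertex in input indexing.
    """
    from .ring_search import fragments, isolated_ring_systems, ring_search

    part = ring_search(g)
    cycles: list[Cycle] = list(isolated_ring_systems(g, part))
    info: list[ComponentInfo] = []
    for cid, frag in enumerate(fragments(g, part)):
        comp = frag.component
        info.append(
            ComponentInfo(
                component_id=cid,
                n_vertices=len(comp.vertices),
                n_edges=comp.edge_set.popcount(),
                simple=comp.is_simple,
                skipped=comp.is_simple,
            )
        )
        if comp.is_simple:
            continue
        try:
            sub = path_graph_cycles(frag.graph, max_degree)
        except FeasibilityError as exc:
            f = exc.feasibility
            raise FeasibilityError(
                frag.to_parent[f.offending_vertex], f.degree_reached, max_degree
            ) from None
        cycles.extend(frag.map_cycle(c, g) for c in sub)
    return CycleSetResult(
        method="all",
        cycles=tuple(sorted(cycles)),
        per_component=tuple(info),
        feasibility=Feasibility(max_degree=max_degree),
    )
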