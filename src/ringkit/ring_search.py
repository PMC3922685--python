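"""Cycle membership and ring-system partitioning.

A single iterative depth-first search finds the biconnected components of
the graph.  Bridge components (one edge) are acyclic and dropped; the rest
are the ring systems of the structure.  A component with |E| = |V| has
circuit rank 1 and *is* one elementary cycle — an isolated or spiro ring —
and is classified "simple"; fused and bridged systems (|E| > |V|) are
"non-simple" and are the only parts that need the heavier cycle algorithms.

Membership is tracked with bit sets over the vertex/edge index spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_core import Cycle, EdgeBitSet, MolGraph, build_graph

__all__ = [
    "BiconnComponent",
    "RingPartition",
    "Fragment",
    "ring_search",
    "isolated_ring_systems",
    "fragments",
]


@dataclass(frozen=True)
class BiconnComponent:
    """One biconnected component with at least one cycle."""

    vertices: frozenset[int]
    edge_set: EdgeBitSet
    is_simple: bool

    @property
    def circuit_rank(self) -> int:
        # a biconnected component is connected, so rank = |E| - |V| + 1
        return self.edge_set.popcount() - len(self.vertices) + 1


@dataclass(frozen=True)
class RingPartition:
    """Cyclic membership plus the classified biconnected components.

    ``components`` excludes bridges: every cyclic edge belongs to exactly one
    listed component, and a vertex is cyclic iff it belongs to at least one
    component (articulation vertices may belong to several).
    """

    cyclic_vertices: frozenset[int]
    cyclic_edges: EdgeBitSet
    components: tuple[BiconnComponent, ...]

    def is_cyclic_vertex(self, v: int) -> bool:
        return v in self.cyclic_vertices

    def is_cyclic_edge(self, edge_index: int) -> bool:
        return edge_index in self.cyclic_edges


def _biconnected_edge_groups(g: MolGraph) -> list[list[int]]:
    """Edge-index groups of the biconnected components (single iterative DFS)."""
    n = g.n_vertices
    disc = [-1] * n
    low = [0] * n
    timer = 0
    groups: list[list[int]] = []
    edge_stack: list[int] = []
    for root in range(n):
        if disc[root] != -1:
            continue
        disc[root] = low[root] = timer
        timer += 1
        # frame: (vertex, parent edge index, adjacency iterator)
        stack = [(root, -1, iter(g.adjacency[root]))]
        while stack:
            v, parent_edge, it = stack[-1]
            descended = False
            for w, ei in it:
                if ei == parent_edge:
                    continue
                if disc[w] == -1:
                    edge_stack.append(ei)
                    disc[w] = low[w] = timer
                    timer += 1
                    stack.append((w, ei, iter(g.adjacency[w])))
                    descended = True
                    break
                if disc[w] < disc[v]:  # back edge to an ancestor
                    edge_stack.append(ei)
                    if disc[w] < low[v]:
                        low[v] = disc[w]
            if descended:
                continue
            stack.pop()
            if not stack:
                continue
            u = stack[-1][0]
            if low[v] < low[u]:
                low[u] = low[v]
            if low[v] >= disc[u]:
                # u is an articulation point (or the root): pop one component
                group: list[int] = []
                while True:
                    ei = edge_stack.pop()
                    group.append(ei)
                    if ei == parent_edge:
                        break
                groups.append(group)
    return groups


def ring_search(g: MolGraph) -> RingPartition:
    """Determine cyclic vertices/edges and classify the ring systems.

    Bridge edges (single-edge biconnected components) are acyclic and are
    excluded from the component list.
    """
    components: list[BiconnComponent] = []
    cyclic_vertices: set[int] = set()
    cyclic_bits = 0
    for group in _biconnected_edge_groups(g):
        if len(group) < 2:
            continue  # bridge: acyclic
        verts: set[int] = set()
        bits = 0
        for ei in group:
            u, v = g.edges[ei]
            verts.add(u)
            verts.add(v)
            bits |= 1 << ei
        components.append(
            BiconnComponent(
                vertices=frozenset(verts),
                edge_set=EdgeBitSet(g.n_edges, bits),
                is_simple=len(group) == len(verts),
            )
        )
        cyclic_vertices |= verts
        cyclic_bits |= bits
    return RingPartition(
        cyclic_vertices=frozenset(cyclic_vertices),
        cyclic_edges=EdgeBitSet(g.n_edges, cyclic_bits),
        components=tuple(components),
    )


def isolated_ring_systems(g: MolGraph, p: RingPartition) -> list[Cycle]:
    """The single elementary cycle of each simple component.

    Walks start at the component's minimum vertex index and step toward its
    smaller-indexed neighbour, giving a deterministic orientation.
    """
    cycles: list[Cycle] = []
    for comp in p.components:
        if not comp.is_simple:
            continue
        cycles.append(_trace_simple_cycle(g, comp))
    return cycles


def _trace_simple_cycle(g: MolGraph, comp: BiconnComponent) -> Cycle:
    start = min(comp.vertices)
    in_comp = comp.edge_set
    walk = [start]
    prev = -1
    v = start
    while True:
        nbrs = sorted(
            w for w, ei in g.adjacency[v] if ei in in_comp and w != prev
        )
        if not nbrs:  # only possible on the way back to start via prev
            nbrs = [prev]
        nxt = nbrs[0]
        if nxt == start:
            break
        walk.append(nxt)
        prev, v = v, nxt
    return Cycle.from_vertices(g, walk)


@dataclass(frozen=True)
class Fragment:
    """An induced subgraph of one biconnected component.

    ``to_parent[i]`` maps the fragment's vertex ``i`` back to the input
    graph's vertex index.
    """

    graph: MolGraph
    to_parent: tuple[int, ...]
    component: BiconnComponent

    def map_cycle(self, cycle: Cycle, parent: MolGraph) -> Cycle:
        """Re-express a fragment cycle in the parent graph's indexing."""
        verts = [self.to_parent[v] for v in cycle.vertices()]
        return Cycle.from_vertices(parent, verts)


def fragments(g: MolGraph, p: RingPartition) -> list[Fragment]:
    """One induced subgraph per biconnected component, with vertex mapping."""
    out: list[Fragment] = []
    for comp in p.components:
        to_parent = tuple(sorted(comp.vertices))
        back = {v: i for i, v in enumerate(to_parent)}
        sub_edges = []
        for ei in comp.edge_set.indices():
            u, v = g.edges[ei]
            sub_edges.append((back[u], back[v]))
        out.append(
            Fragment(
                graph=build_graph(len(to_parent), sub_edges),
                to_parent=to_parent,
                component=comp,
            )
        )
    return out
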