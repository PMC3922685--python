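"""Deliberately naive brute-force reference implementations.

These oracles share no cycle-finding logic with the production modules:
cycle enumeration is a plain DFS over paths anchored at their minimum
vertex, and the set of all minimum cycle bases is found by exhaustive
subset search over the enumerated cycles.  They are exponential and guarded
to small graphs; they exist to define ground truth in tests.
"""

from __future__ import annotations

import itertools
import random
from typing import Iterable

from .graph_core import Cycle, MolGraph, build_graph

__all__ = [
    "enumerate_all_cycles_bruteforce",
    "all_mcbs_bruteforce",
    "relevant_cycles_bruteforce",
    "essential_cycles_bruteforce",
    "shortest_cycles_through_vertex_bruteforce",
    "random_graph",
    "random_connected_graph",
]


def enumerate_all_cycles_bruteforce(g: MolGraph, max_vertices: int = 16) -> list[Cycle]:
    """Exhaustive elementary-cycle enumeration.

    For each start vertex s, DFS extends paths using only vertices > s, so
    every cycle is found exactly once anchored at its minimum vertex; the
    two traversal directions are collapsed by requiring the second vertex of
    the path to be smaller than the last.
    """
    if g.n_vertices > max_vertices:
        raise ValueError(
            f"brute-force enumeration guarded to {max_vertices} vertices"
        )
    cycles: list[Cycle] = []
    for s in range(g.n_vertices):
        stack: list[list[int]] = [[s]]
        while stack:
            path = stack.pop()
            v = path[-1]
            for w in g.neighbours(v):
                if w == s and len(path) >= 3:
                    if path[1] < path[-1]:
                        cycles.append(Cycle.from_vertices(g, path))
                elif w > s and w not in path:
                    stack.append(path + [w])
    return sorted(cycles)


def _gf2_rank(vectors: Iterable[int]) -> int:
    rows: dict[int, int] = {}
    rank = 0
    for v in vectors:
        while v:
            p = v.bit_length() - 1
            if p in rows:
                v ^= rows[p]
            else:
                rows[p] = v
                rank += 1
                break
    return rank


def _min_basis_weight(cycles: list[Cycle], rank: int) -> int:
    """Greedy over all cycles sorted by weight gives a minimum-weight basis
    (matroid greedy); returns its total weight."""
    rows: dict[int, int] = {}
    total = 0
    count = 0
    for c in sorted(cycles, key=lambda c: c.weight):
        v = c.edge_bits.bits
        while v:
            p = v.bit_length() - 1
            if p in rows:
                v ^= rows[p]
            else:
                rows[p] = v
                total += c.weight
                count += 1
                break
        if count == rank:
            break
    return total


def all_mcbs_bruteforce(
    g: MolGraph, max_rank: int = 6, max_cycles: int = 40
) -> list[tuple[Cycle, ...]]:
    """Every minimum-weight cycle basis, by exhaustive subset search.

    Subsets are enumerated per weight-multiset to keep the search tractable;
    guarded by circuit rank and total cycle count.
    """
    cycles = enumerate_all_cycles_bruteforce(g)
    rank = _gf2_rank(c.edge_bits.bits for c in cycles)
    if rank == 0:
        return [()]
    if rank > max_rank:
        raise ValueError(f"circuit rank {rank} exceeds guard {max_rank}")
    if len(cycles) > max_cycles:
        raise ValueError(f"{len(cycles)} cycles exceeds guard {max_cycles}")
    min_weight = _min_basis_weight(cycles, rank)
    by_weight: dict[int, list[Cycle]] = {}
    for c in cycles:
        by_weight.setdefault(c.weight, []).append(c)
    weights = sorted(by_weight)
    bases: list[tuple[Cycle, ...]] = []

    def pick(i: int, remaining: int, budget: int, chosen: list[list[Cycle]]) -> None:
        if remaining == 0:
            if budget == 0:
                for combo in itertools.product(*chosen):
                    flat = [c for group in combo for c in group]
                    if _gf2_rank(c.edge_bits.bits for c in flat) == rank:
                        bases.append(tuple(sorted(flat)))
            return
        if i == len(weights):
            return
        w = weights[i]
        avail = by_weight[w]
        max_take = min(len(avail), remaining, budget // w)
        for take in range(max_take + 1):
            if take * w <= budget:
                groups = (
                    [list(c) for c in itertools.combinations(avail, take)]
                    if take
                    else [[]]
                )
                pick(i + 1, remaining - take, budget - take * w, chosen + [groups])

    pick(0, rank, min_weight, [])
    return bases


def relevant_cycles_bruteforce(g: MolGraph, **guards) -> set:
    """Union of all brute-force MCBs, as a set of edge bit sets."""
    out = set()
    for basis in all_mcbs_bruteforce(g, **guards):
        out |= {c.edge_bits for c in basis}
    return out


def essential_cycles_bruteforce(g: MolGraph, **guards) -> set:
    """Intersection of all brute-force MCBs, as a set of edge bit sets."""
    bases = all_mcbs_bruteforce(g, **guards)
    out = {c.edge_bits for c in bases[0]}
    for basis in bases[1:]:
        out &= {c.edge_bits for c in basis}
    return out


def shortest_cycles_through_vertex_bruteforce(g: MolGraph, v: int) -> set:
    """Edge bit sets of all minimum-weight cycles containing v."""
    through = [c for c in enumerate_all_cycles_bruteforce(g) if v in c.vertices()]
    if not through:
        return set()
    w = min(c.weight for c in through)
    return {c.edge_bits for c in through if c.weight == w}


def random_graph(n: int, p: float, seed: int) -> MolGraph:
    """Seeded Erdos-Renyi G(n, p) simple graph; reproducible."""
    rng = random.Random(seed)
    edges = [
        (u, v)
        for u in range(n)
        for v in range(u + 1, n)
        if rng.random() < p
    ]
    return build_graph(n, edges)


def random_connected_graph(n: int, extra_edges: int, seed: int) -> MolGraph:
    """Random spanning tree plus ``extra_edges`` distinct chords.

    Molecule-like sparse test graphs: connected, circuit rank exactly
    min(extra_edges, C(n,2) - (n-1)).
    """
    rng = random.Random(seed)
    perm = list(range(n))
    rng.shuffle(perm)
    edges: set[tuple[int, int]] = set()
    for i in range(1, n):
        u = perm[i]
        v = perm[rng.randrange(i)]
        edges.add((u, v) if u < v else (v, u))
    candidates = [
        (u, v)
        for u in range(n)
        for v in range(u + 1, n)
        if (u, v) not in edges
    ]
    rng.shuffle(candidates)
    edges.update(candidates[:extra_edges])
    return build_graph(n, sorted(edges))
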