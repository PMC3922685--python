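"""Front-end for ring perception with preprocessing.

``cycles`` runs the biconnected ring search first: simple components (a
single isolated or spiro ring) contribute their one cycle directly and are
skipped by the heavier algorithms; non-simple components are dispatched to
the requested algorithm on their induced fragment, with searches restricted
to degree > 2 vertices where valid.  Results are mapped back to input-graph
indexing and merged.  Preprocessing is an optimisation only — for every
method the result equals the direct whole-graph computation.
"""

from __future__ import annotations

from typing import Optional

from . import short_cycles as _short
from .all_cycles import DEFAULT_MAX_DEGREE, path_graph_cycles
from .graph_core import (
    ComponentInfo,
    Cycle,
    CycleSetResult,
    EdgeBitSet,
    Feasibility,
    FeasibilityError,
    MolGraph,
    RelevantCountError,
)
from .ring_search import Fragment, fragments, ring_search

__all__ = ["METHODS", "cycles", "cycles_or_fallback"]

METHODS = (
    "mcb",
    "relevant",
    "essential",
    "all",
    "vertex_short",
    "edge_short",
    "triplet",
)


def _component_cycles(
    frag: Fragment,
    method: str,
    max_degree: int,
    relevant_limit: Optional[int],
    unique: bool,
) -> list[Cycle]:
    g = frag.graph
    if method == "all":
        return path_graph_cycles(g, max_degree)
    if method == "triplet":
        return list(_short.triplet_cycles(g, unique=unique).cycles)
    init = _short.InitialCycles(g, only_branch_vertices=True)
    if method == "mcb":
        rank = g.n_edges - g.n_vertices + 1
        return list(
            _short._greedy_basis(init.families, rank, g.n_edges).cycles
        )
    rel = _short._relevant_families(init.families)
    if method == "relevant":
        return _short._enumerate_relevant(g, rel, relevant_limit)
    if method == "essential":
        return _short._essential_from_relevant(rel)
    if method in ("vertex_short", "edge_short"):
        members = _short._enumerate_relevant(g, rel, relevant_limit)
        best: dict[object, int] = {}
        key_of = (
            (lambda c: c.vertices())
            if method == "vertex_short"
            else (lambda c: c.edge_bits.indices())
        )
        for c in members:
            for k in key_of(c):
                if best.get(k) is None or c.weight < best[k]:
                    best[k] = c.weight
        chosen: dict[EdgeBitSet, Cycle] = {}
        for c in members:
            for k in key_of(c):
                if best[k] == c.weight:
                    chosen.setdefault(c.edge_bits, c)
        return sorted(chosen.values())
    raise ValueError(f"unknown method {method!r}")


def cycles(
    g: MolGraph,
    method: str,
    *,
    max_degree: int = DEFAULT_MAX_DEGREE,
    relevant_limit: Optional[int] = _short.DEFAULT_RELEVANT_LIMIT,
    unique: bool = True,
) -> CycleSetResult:
    """Compute the named cycle set with biconnected preprocessing.

    ``method`` is one of :data:`METHODS`.  Feasibility errors ("all" over
    the degree threshold, "relevant" over the count limit) propagate; use
    :func:`cycles_or_fallback` to absorb them.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    part = ring_search(g)
    out: list[Cycle] = []
    info: list[ComponentInfo] = []
    for cid, frag in enumerate(fragments(g, part)):
        comp = frag.component
        simple = comp.is_simple
        info.append(
            ComponentInfo(
                component_id=cid,
                n_vertices=len(comp.vertices),
                n_edges=comp.edge_set.popcount(),
                simple=simple,
                skipped=simple,
            )
        )
        if simple:
            from .ring_search import _trace_simple_cycle

            cyc = _trace_simple_cycle(g, comp)
            if method == "triplet" and not unique:
                out.extend([cyc] * len(comp.vertices))  # one per triple
            else:
                out.append(cyc)
            continue
        try:
            sub = _component_cycles(frag, method, max_degree, relevant_limit, unique)
        except FeasibilityError as exc:
            f = exc.feasibility
            raise FeasibilityError(
                frag.to_parent[f.offending_vertex], f.degree_reached, max_degree
            ) from None
        out.extend(frag.map_cycle(c, g) for c in sub)
    if not (method == "triplet" and not unique):
        dedup: dict[EdgeBitSet, Cycle] = {}
        for c in sorted(out):
            dedup.setdefault(c.edge_bits, c)
        out = list(dedup.values())
    return CycleSetResult(
        method=method,
        cycles=tuple(sorted(out)),
        per_component=tuple(info),
        feasibility=Feasibility(max_degree=max_degree) if method == "all" else None,
    )


def cycles_or_fallback(
    g: MolGraph,
    preferred: str,
    fallback: str,
    **options,
) -> CycleSetResult:
    """Preferred cycle set when feasible, else the fallback set.

    When the preferred computation trips its feasibility guard the fallback
    method's result is returned with ``fallback_used`` set to
    ``"preferred→fallback"`` and the feasibility record attached.
    """
    try:
        return cycles(g, preferred, **options)
    except FeasibilityError as exc:
        feas = exc.feasibility
    except RelevantCountError:
        feas = None
    result = cycles(g, fallback, **options)
    return CycleSetResult(
        method=result.method,
        cycles=result.cycles,
        per_component=result.per_component,
        feasibility=feas,
        fallback_used=f"{preferred}→{fallback}",
    )
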