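"""Named molecular test fixtures, built programmatically.

Each fixture is the heavy-atom connectivity graph of a named structure
(hydrogens omitted), with per-method expected cycle counts where these are
established by construction.  The C60 fullerene is generated procedurally
as the truncated icosahedron rather than read from a file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .graph_core import MolGraph, build_graph

__all__ = ["FixtureMolecule", "named_fixture", "fixture_names", "FIXTURES"]


@dataclass(frozen=True)
class FixtureMolecule:
    name: str
    graph: MolGraph
    expected: dict[str, int] = field(default_factory=dict)


def _ring(n: int) -> list[tuple[int, int]]:
    return [(i, (i + 1) % n) for i in range(n)]


def _barrelene() -> MolGraph:
    # bridgeheads 0, 1 joined by three 2-vertex bridges
    edges = [(0, 2), (2, 3), (3, 1), (0, 4), (4, 5), (5, 1), (0, 6), (6, 7), (7, 1)]
    return build_graph(8, edges)


def _naphthalene() -> MolGraph:
    # two hexagons fused on edge (0, 1)
    edges = _ring(6) + [(1, 6), (6, 7), (7, 8), (8, 9), (9, 0)]
    return build_graph(10, edges)


def _anthracene() -> MolGraph:
    # three linearly fused hexagons; fusion edges (2,3) and (7,8)
    edges = _ring(6)
    edges += [(3, 6), (6, 7), (7, 8), (8, 9), (9, 2)]
    edges += [(8, 10), (10, 11), (11, 12), (12, 13), (13, 7)]
    return build_graph(14, edges)


def _azulene() -> MolGraph:
    # 5-ring 0-1-2-3-4 and 7-ring 0-1-5-6-7-8-9 fused on edge (0, 1)
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]
    edges += [(1, 5), (5, 6), (6, 7), (7, 8), (8, 9), (9, 0)]
    return build_graph(10, edges)


def _cubane() -> MolGraph:
    edges = _ring(4) + [(i + 4, (i + 1) % 4 + 4) for i in range(4)]
    edges += [(i, i + 4) for i in range(4)]
    return build_graph(8, edges)


def _biphenyl() -> MolGraph:
    edges = _ring(6) + [(u + 6, v + 6) for u, v in _ring(6)] + [(0, 6)]
    return build_graph(12, edges)


def _cumene() -> MolGraph:
    # propan-2-ylbenzene: benzene ring 0..5 with isopropyl 6 (CH), 7, 8
    edges = _ring(6) + [(0, 6), (6, 7), (6, 8)]
    return build_graph(9, edges)


def _cyclohexane() -> MolGraph:
    return build_graph(6, _ring(6))


def _spiro_decane() -> MolGraph:
    # spiro[4.5]decane: 5-ring and 6-ring sharing only vertex 0
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]
    edges += [(0, 5), (5, 6), (6, 7), (7, 8), (8, 9), (9, 0)]
    return build_graph(10, edges)


def _icosahedron_coords() -> list[tuple[float, float, float]]:
    phi = (1 + math.sqrt(5)) / 2
    coords = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            coords.append((0.0, a, b))
            coords.append((a, b, 0.0))
            coords.append((b, 0.0, a))
    return coords


def _c60() -> MolGraph:
    """Truncated icosahedron: each icosahedron vertex becomes a pentagon of
    its five (vertex, incident-edge) corners, joined around the vertex in
    angular order; each icosahedron edge contributes one inter-pentagon
    bond.  60 vertices, 90 edges, 3-regular."""
    coords = _icosahedron_coords()
    n = len(coords)
    edge_len_sq = 4.0  # icosahedron edge length with these coordinates is 2

    def close(i: int, j: int) -> bool:
        d = sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3))
        return abs(d - edge_len_sq) < 1e-6

    nbrs = [[j for j in range(n) if j != i and close(i, j)] for i in range(n)]
    corner_index: dict[tuple[int, int], int] = {}
    for v in range(n):
        for u in nbrs[v]:
            corner_index[(v, u)] = len(corner_index)
    edges: set[tuple[int, int]] = set()

    def add(a: int, b: int) -> None:
        edges.add((a, b) if a < b else (b, a))

    for v in range(n):
        # order the five neighbours angularly around the axis through v
        vx, vy, vz = coords[v]
        norm = math.sqrt(vx * vx + vy * vy + vz * vz)
        ax = (vx / norm, vy / norm, vz / norm)
        ref = (1.0, 0.0, 0.0) if abs(ax[0]) < 0.9 else (0.0, 1.0, 0.0)
        # orthonormal basis of the plane perpendicular to v
        b1 = _cross(ax, ref)
        b1 = _scale(b1, 1 / _norm(b1))
        b2 = _cross(ax, b1)
        ordered = sorted(
            nbrs[v],
            key=lambda u: math.atan2(
                _dot(coords[u], b2), _dot(coords[u], b1)
            ),
        )
        for i, u in enumerate(ordered):
            w = ordered[(i + 1) % len(ordered)]
            add(corner_index[(v, u)], corner_index[(v, w)])
    for v in range(n):
        for u in nbrs[v]:
            if v < u:
                add(corner_index[(v, u)], corner_index[(u, v)])
    return build_graph(len(corner_index), sorted(edges))


def _dot(a, b) -> float:
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a, b):
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def _norm(a) -> float:
    return math.sqrt(_dot(a, a))


def _scale(a, s: float):
    return (a[0] * s, a[1] * s, a[2] * s)


_BUILDERS = {
    "barrelene": _barrelene,
    "naphthalene": _naphthalene,
    "anthracene": _anthracene,
    "azulene": _azulene,
    "cubane": _cubane,
    "biphenyl": _biphenyl,
    "propan-2-ylbenzene": _cumene,
    "cyclohexane": _cyclohexane,
    "spiro-decane": _spiro_decane,
    "c60-fullerene": _c60,
}

# counts established by construction / exhaustive reasoning on the named graph
_EXPECTED: dict[str, dict[str, int]] = {
    "barrelene": {"mcb": 2, "relevant": 3, "essential": 0, "all": 3,
                  "vertex_short": 3, "edge_short": 3},
    "naphthalene": {"mcb": 2, "relevant": 2, "essential": 2, "all": 3,
                    "vertex_short": 2, "edge_short": 2},
    "anthracene": {"mcb": 3, "relevant": 3, "essential": 3, "all": 6},
    "azulene": {"mcb": 2, "relevant": 2, "essential": 2, "all": 3,
                "edge_short": 2},
    "cubane": {"mcb": 5, "relevant": 6, "essential": 0},
    "biphenyl": {"mcb": 2, "relevant": 2, "essential": 2, "all": 2},
    "propan-2-ylbenzene": {"mcb": 1, "relevant": 1, "essential": 1, "all": 1},
    "cyclohexane": {"mcb": 1, "relevant": 1, "essential": 1, "all": 1,
                    "vertex_short": 1, "edge_short": 1, "triplet": 1},
    "spiro-decane": {"mcb": 2, "relevant": 2, "essential": 2, "all": 2},
    "c60-fullerene": {"mcb": 31, "relevant": 32, "essential": 12},
}

FIXTURES = tuple(_BUILDERS)


def fixture_names() -> tuple[str, ...]:
    return FIXTURES


def named_fixture(name: str) -> FixtureMolecule:
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURES)}"
        ) from None
    return FixtureMolecule(name=name, graph=builder(), expected=dict(_EXPECTED.get(name, {})))
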