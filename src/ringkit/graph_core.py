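"""Graph model and shared value types for ring perception.

A chemical structure is modelled as a simple undirected labelled graph:
atoms are vertices, bonds are edges.  Element symbols and bond orders are
carried as labels but never consulted by any algorithm — the graph is
unweighted.  Vertex indices are 0-based throughout; edge indices are
assigned in input order and are the canonical coordinate system for the
GF(2) edge bit vectors used by every cycle algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "GraphError",
    "MolfileParseError",
    "EdgeBitSet",
    "MolGraph",
    "Cycle",
    "Feasibility",
    "FeasibilityError",
    "RelevantCountError",
    "ComponentInfo",
    "CycleSetResult",
    "build_graph",
    "circuit_rank",
    "xor_cycles",
    "read_molfile",
    "read_sdf",
    "read_smiles",
    "read_graph_text",
]


class GraphError(ValueError):
    """Invalid graph construction or use (loops, multi-edges, bad indices)."""


class MolfileParseError(GraphError):
    """Malformed molfile input; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class EdgeBitSet:
    """A GF(2) vector over the edge-index space of one graph.

    The width is the number of edges of the owning graph; XOR of two sets of
    the same width is the symmetric difference of the edge sets, which for two
    cycles sharing at least one edge yields a cycle or an edge-disjoint union
    of cycles.
    """

    __slots__ = ("bits", "width")

    def __init__(self, width: int, bits: int = 0):
        if bits < 0 or bits >> width:
            raise GraphError(f"bits out of range for width {width}")
        self.bits = bits
        self.width = width

    @classmethod
    def from_indices(cls, width: int, indices: Iterable[int]) -> "EdgeBitSet":
        bits = 0
        for i in indices:
            if not 0 <= i < width:
                raise GraphError(f"edge index {i} out of range for width {width}")
            bits |= 1 << i
        return cls(width, bits)

    def _check(self, other: "EdgeBitSet") -> None:
        if not isinstance(other, EdgeBitSet):
            raise TypeError("expected EdgeBitSet")
        if other.width != self.width:
            raise GraphError(
                f"width mismatch: {self.width} != {other.width}"
            )

    def __xor__(self, other: "EdgeBitSet") -> "EdgeBitSet":
        self._check(other)
        return EdgeBitSet(self.width, self.bits ^ other.bits)

    def __and__(self, other: "EdgeBitSet") -> "EdgeBitSet":
        self._check(other)
        return EdgeBitSet(self.width, self.bits & other.bits)

    def __or__(self, other: "EdgeBitSet") -> "EdgeBitSet":
        self._check(other)
        return EdgeBitSet(self.width, self.bits | other.bits)

    def popcount(self) -> int:
        return self.bits.bit_count()

    def __len__(self) -> int:
        return self.bits.bit_count()

    def __contains__(self, index: int) -> bool:
        return 0 <= index < self.width and bool(self.bits >> index & 1)

    def indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.width) if self.bits >> i & 1)

    def issubset(self, other: "EdgeBitSet") -> bool:
        self._check(other)
        return self.bits & ~other.bits == 0

    def __bool__(self) -> bool:
        return self.bits != 0

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EdgeBitSet)
            and other.width == self.width
            and other.bits == self.bits
        )

    def __hash__(self) -> int:
        return hash((self.width, self.bits))

    def __repr__(self) -> str:
        return f"EdgeBitSet(width={self.width}, edges={list(self.indices())})"


class MolGraph:
    """Immutable simple undirected graph with adjacency and incidence views.

    Both views are built once at construction (the one-time conversion that
    all algorithms then share) and are consistent with the edge list:
    ``adjacency[v]`` is a tuple of ``(neighbour, edge_index)`` pairs and
    ``incidence[v]`` the tuple of incident edge indices.
    """

    __slots__ = (
        "n_vertices",
        "edges",
        "vertex_labels",
        "edge_labels",
        "adjacency",
        "incidence",
        "_edge_index",
    )

    def __init__(
        self,
        n_vertices: int,
        edges: Sequence[tuple[int, int]],
        vertex_labels: Optional[Sequence[str]] = None,
        edge_labels: Optional[Sequence[object]] = None,
    ):
        if n_vertices < 0:
            raise GraphError("negative vertex count")
        norm: list[tuple[int, int]] = []
        index: dict[tuple[int, int], int] = {}
        adjacency: list[list[tuple[int, int]]] = [[] for _ in range(n_vertices)]
        for ei, (u, v) in enumerate(edges):
            if not (0 <= u < n_vertices and 0 <= v < n_vertices):
                raise GraphError(f"edge ({u}, {v}) has endpoint outside [0, {n_vertices})")
            if u == v:
                raise GraphError(f"edge ({u}, {v}) is a loop")
            key = (u, v) if u < v else (v, u)
            if key in index:
                raise GraphError(f"duplicate edge ({u}, {v})")
            index[key] = ei
            norm.append(key)
            adjacency[u].append((v, ei))
            adjacency[v].append((u, ei))
        if vertex_labels is not None and len(vertex_labels) != n_vertices:
            raise GraphError("vertex_labels length mismatch")
        if edge_labels is not None and len(edge_labels) != len(norm):
            raise GraphError("edge_labels length mismatch")
        self.n_vertices = n_vertices
        self.edges: tuple[tuple[int, int], ...] = tuple(norm)
        self.vertex_labels = tuple(vertex_labels) if vertex_labels is not None else None
        self.edge_labels = tuple(edge_labels) if edge_labels is not None else None
        self.adjacency: tuple[tuple[tuple[int, int], ...], ...] = tuple(
            tuple(a) for a in adjacency
        )
        self.incidence: tuple[tuple[int, ...], ...] = tuple(
            tuple(ei for _, ei in a) for a in adjacency
        )
        self._edge_index = index

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    def neighbours(self, v: int) -> tuple[int, ...]:
        return tuple(w for w, _ in self.adjacency[v])

    def edge_index(self, u: int, v: int) -> int:
        key = (u, v) if u < v else (v, u)
        try:
            return self._edge_index[key]
        except KeyError:
            raise GraphError(f"no edge ({u}, {v})") from None

    def has_edge(self, u: int, v: int) -> bool:
        key = (u, v) if u < v else (v, u)
        return key in self._edge_index

    def empty_edge_set(self) -> EdgeBitSet:
        return EdgeBitSet(self.n_edges)

    def edge_set(self, indices: Iterable[int]) -> EdgeBitSet:
        return EdgeBitSet.from_indices(self.n_edges, indices)

    def connected_components(self) -> list[list[int]]:
        """Vertex lists of connected components, iterative DFS."""
        seen = [False] * self.n_vertices
        comps: list[list[int]] = []
        for start in range(self.n_vertices):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            stack = [start]
            while stack:
                v = stack.pop()
                for w, _ in self.adjacency[v]:
                    if not seen[w]:
                        seen[w] = True
                        comp.append(w)
                        stack.append(w)
            comps.append(comp)
        return comps

    def __repr__(self) -> str:
        return f"MolGraph(n_vertices={self.n_vertices}, n_edges={self.n_edges})"


def build_graph(
    n_vertices: int,
    edges: Sequence[tuple[int, int]],
    vertex_labels: Optional[Sequence[str]] = None,
    edge_labels: Optional[Sequence[object]] = None,
) -> MolGraph:
    """Validate and build a :class:`MolGraph`.

    Rejects loops, duplicate unordered edges and out-of-range endpoints,
    naming the offending edge in the error.
    """
    return MolGraph(n_vertices, edges, vertex_labels, edge_labels)


def circuit_rank(g: MolGraph) -> int:
    """|E| - |V| + |ConnComp(G)|: the number of independent cycles.

    Equals the size of any minimum cycle basis; also called the cyclomatic
    number.  Additive over connected components.
    """
    return g.n_edges - g.n_vertices + len(g.connected_components())


def xor_cycles(a: EdgeBitSet, b: EdgeBitSet) -> EdgeBitSet:
    """Symmetric difference of two edge sets (GF(2) sum of cycle vectors)."""
    return a ^ b


@dataclass(frozen=True)
class Cycle:
    """One elementary cycle: a closed vertex walk plus its edge bit vector.

    The walk is canonically oriented (starts at the minimum vertex index and
    proceeds toward its smaller-indexed cycle neighbour) so equal cycles
    compare and print identically.
    """

    walk: tuple[int, ...]
    edge_bits: EdgeBitSet

    @property
    def weight(self) -> int:
        return len(self.walk) - 1

    def vertices(self) -> tuple[int, ...]:
        return self.walk[:-1]

    @classmethod
    def from_vertices(cls, g: MolGraph, vertices: Sequence[int]) -> "Cycle":
        """Build from an open vertex sequence v0..vk-1 tracing the cycle."""
        k = len(vertices)
        if k < 3:
            raise GraphError("a cycle needs at least 3 vertices")
        if len(set(vertices)) != k:
            raise GraphError("cycle walk repeats a vertex")
        pos = min(range(k), key=lambda i: vertices[i])
        nxt = vertices[(pos + 1) % k]
        prv = vertices[(pos - 1) % k]
        if prv < nxt:  # orient toward the smaller-indexed neighbour
            ordered = [vertices[(pos - i) % k] for i in range(k)]
        else:
            ordered = [vertices[(pos + i) % k] for i in range(k)]
        ordered.append(ordered[0])
        bits = g.edge_set(
            g.edge_index(ordered[i], ordered[i + 1]) for i in range(k)
        )
        if bits.popcount() != k:
            raise GraphError("cycle walk repeats an edge")
        return cls(tuple(ordered), bits)

    def __lt__(self, other: "Cycle") -> bool:
        return (self.weight, self.walk) < (other.weight, other.walk)

    def __repr__(self) -> str:
        return f"Cycle({'-'.join(map(str, self.walk))})"


@dataclass(frozen=True)
class Feasibility:
    """Outcome of the machine-independent degree-threshold check.

    ``max_degree`` defaults to 684 elsewhere; values above 5000 are allowed
    but lie beyond the tested range.
    """

    max_degree: int
    exceeded: bool = False
    offending_vertex: Optional[int] = None
    degree_reached: Optional[int] = None


class FeasibilityError(RuntimeError):
    """Raised when the all-cycles path graph exceeds the degree threshold.

    Deterministic: the same input and threshold always fail identically.
    """

    def __init__(self, vertex: int, degree: int, max_degree: int):
        super().__init__(
            f"path-graph degree {degree} at vertex {vertex} exceeds "
            f"threshold {max_degree}"
        )
        self.feasibility = Feasibility(
            max_degree=max_degree,
            exceeded=True,
            offending_vertex=vertex,
            degree_reached=degree,
        )


class RelevantCountError(RuntimeError):
    """Raised when the relevant-cycle count exceeds the enumeration guard."""

    def __init__(self, count: int, limit: int):
        super().__init__(f"{count} relevant cycles exceeds limit {limit}")
        self.count = count
        self.limit = limit


@dataclass(frozen=True)
class ComponentInfo:
    """Provenance for one biconnected component in a facade result."""

    component_id: int
    n_vertices: int
    n_edges: int
    simple: bool
    skipped: bool


@dataclass(frozen=True)
class CycleSetResult:
    """A named cycle set in input-graph vertex indexing."""

    method: str
    cycles: tuple[Cycle, ...]
    per_component: tuple[ComponentInfo, ...] = ()
    feasibility: Optional[Feasibility] = None
    fallback_used: Optional[str] = None

    def __len__(self) -> int:
        return len(self.cycles)

    def weights(self) -> tuple[int, ...]:
        return tuple(c.weight for c in self.cycles)

    def edge_sets(self) -> frozenset[EdgeBitSet]:
        return frozenset(c.edge_bits for c in self.cycles)


# ---------------------------------------------------------------------------
# Input formats
# ---------------------------------------------------------------------------

def read_molfile(text: str) -> MolGraph:
    """Parse a single MDL molfile (V2000) into a MolGraph.

    One vertex per atom line — explicit hydrogens included — and one edge per
    bond line; the molfile's 1-based atom numbers become 0-based vertex
    indices.  The properties block is skipped.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError("molfile shorter than header + counts line", len(lines))
    counts_no = 4
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolfileParseError(f"malformed counts line {counts!r}", counts_no) from None
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileParseError(
            f"expected {n_atoms} atom and {n_bonds} bond lines", len(lines)
        )
    symbols: list[str] = []
    for i in range(n_atoms):
        line_no = 5 + i
        line = lines[4 + i]
        if len(line) < 34:
            raise MolfileParseError(f"atom line too short: {line!r}", line_no)
        symbols.append(line[31:34].strip())
    edges: list[tuple[int, int]] = []
    orders: list[int] = []
    seen: set[tuple[int, int]] = set()
    for i in range(n_bonds):
        line_no = 5 + n_atoms + i
        line = lines[4 + n_atoms + i]
        try:
            a1 = int(line[0:3])
            a2 = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError):
            raise MolfileParseError(f"malformed bond line: {line!r}", line_no) from None
        for a in (a1, a2):
            if not 1 <= a <= n_atoms:
                raise MolfileParseError(
                    f"bond references atom {a} outside 1..{n_atoms}", line_no
                )
        if a1 == a2:
            raise MolfileParseError(f"bond connects atom {a1} to itself", line_no)
        key = (min(a1, a2), max(a1, a2))
        if key in seen:
            raise MolfileParseError(f"duplicate bond {a1}-{a2}", line_no)
        seen.add(key)
        edges.append((a1 - 1, a2 - 1))
        orders.append(order)
    return build_graph(n_atoms, edges, vertex_labels=symbols, edge_labels=orders)


def read_sdf(text: str) -> Iterator[tuple[str, MolGraph]]:
    """Iterate (title, MolGraph) over the records of an SDF string."""
    for record in text.split("$$$$"):
        record = record.strip("\n")
        if not record.strip():
            continue
        title = record.splitlines()[0].strip()
        yield title, read_molfile(record)


def read_smiles(s: str) -> MolGraph:
    """Parse a SMILES string into a heavy-atom MolGraph.

    Delegates parsing to RDKit; ring-closure bonds become ordinary edges.
    The core algorithms never depend on this ingestion path.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SMILES input requires rdkit (pip install ringkit[smiles])") from exc
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise GraphError(f"unparseable SMILES: {s!r}")
    symbols = [atom.GetSymbol() for atom in mol.GetAtoms()]
    edges = [
        (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()) for bond in mol.GetBonds()
    ]
    orders = [bond.GetBondTypeAsDouble() for bond in mol.GetBonds()]
    return build_graph(mol.GetNumAtoms(), edges, vertex_labels=symbols, edge_labels=orders)


def read_graph_text(text: str) -> MolGraph:
    """Raw graph format: first line ``n m``, then m lines ``u v`` (0-based)."""
    tokens = text.split()
    if len(tokens) < 2:
        raise GraphError("graph text needs an 'n m' header")
    n, m = int(tokens[0]), int(tokens[1])
    if len(tokens) != 2 + 2 * m:
        raise GraphError(f"expected {m} edge lines, got {(len(tokens) - 2) // 2}")
    edges = [
        (int(tokens[2 + 2 * i]), int(tokens[3 + 2 * i])) for i in range(m)
    ]
    return build_graph(n, edges)
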