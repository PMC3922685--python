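"""Graph model, ingestion formats and the circuit-rank formula."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringkit import (
    EdgeBitSet,
    GraphError,
    MolfileParseError,
    build_graph,
    circuit_rank,
    read_graph_text,
    read_molfile,
    read_sdf,
    xor_cycles,
)
from ringkit.fixtures import named_fixture
from ringkit.oracles import enumerate_all_cycles_bruteforce, random_graph

BENZENE_MOLFILE = """benzene
  test

  6  6  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
"""

MINIMAL_MOLFILE = """ethane-like
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
"""


class TestBuildGraph:
    def test_single_edge_path(self):
        g = build_graph(2, [(0, 1)])
        assert [g.degree(v) for v in range(2)] == [1, 1]

    def test_barrelene_structure(self):
        g = named_fixture("barrelene").graph
        assert g.n_vertices == 8
        assert g.n_edges == 9
        assert g.degree(0) == g.degree(1) == 3

    @pytest.mark.parametrize(
        "n, edges",
        [
            (3, [(0, 0)]),            # loop
            (3, [(0, 1), (1, 0)]),    # duplicate unordered pair
            (3, [(0, 3)]),            # endpoint out of range
            (2, [(-1, 0)]),           # negative index
        ],
    )
    def test_invalid_edges_rejected(self, n, edges):
        with pytest.raises(GraphError):
            build_graph(n, edges)

    def test_adjacency_incidence_consistent(self):
        g = named_fixture("naphthalene").graph
        for v in range(g.n_vertices):
            assert g.degree(v) == len(g.adjacency[v]) == len(g.incidence[v])
            for (w, ei), ej in zip(g.adjacency[v], g.incidence[v]):
                assert ei == ej
                assert set(g.edges[ei]) == {v, w}

    def test_round_trip(self):
        g = named_fixture("anthracene").graph
        h = build_graph(g.n_vertices, g.edges)
        assert h.adjacency == g.adjacency
        assert h.incidence == g.incidence
        assert h.edges == g.edges


class TestCircuitRank:
    @pytest.mark.parametrize(
        "name, rank",
        [("barrelene", 2), ("cubane", 5), ("cyclohexane", 1),
         ("naphthalene", 2), ("c60-fullerene", 31)],
    )
    def test_named_structures(self, name, rank):
        assert circuit_rank(named_fixture(name).graph) == rank

    def test_tree_is_acyclic(self):
        g = build_graph(5, [(0, 1), (1, 2), (1, 3), (3, 4)])
        assert circuit_rank(g) == 0

    def test_additive_over_components(self):
        # cyclohexane + cyclopropane as one disconnected graph
        edges = [(i, (i + 1) % 6) for i in range(6)]
        edges += [(6, 7), (7, 8), (6, 8)]
        g = build_graph(9, edges)
        assert circuit_rank(g) == 2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_equals_gf2_rank_of_cycle_space(self, seed):
        g = random_graph(10, 0.25, seed)
        cycles = enumerate_all_cycles_bruteforce(g)
        rows = {}
        rank = 0
        for c in cycles:
            v = c.edge_bits.bits
            while v:
                p = v.bit_length() - 1
                if p in rows:
                    v ^= rows[p]
                else:
                    rows[p] = v
                    rank += 1
                    break
        assert circuit_rank(g) == rank


class TestEdgeBitSet:
    def test_xor_self_inverse(self):
        a = EdgeBitSet.from_indices(8, [1, 3, 5])
        assert not (a ^ a)

    def test_width_mismatch_rejected(self):
        with pytest.raises(GraphError):
            EdgeBitSet(4, 0b1) ^ EdgeBitSet(5, 0b1)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        a=st.integers(0, 2**12 - 1),
        b=st.integers(0, 2**12 - 1),
        c=st.integers(0, 2**12 - 1),
    )
    def test_gf2_vector_axioms(self, a, b, c):
        A, B, C = (EdgeBitSet(12, x) for x in (a, b, c))
        assert A ^ B == B ^ A
        assert (A ^ B) ^ C == A ^ (B ^ C)
        assert (A ^ B) ^ B == A
        assert (A ^ B).popcount() == bin(a ^ b).count("1")

    def test_xor_of_fused_rings_gives_envelope(self, naphthalene):
        cycles = enumerate_all_cycles_bruteforce(naphthalene)
        six = [c for c in cycles if c.weight == 6]
        ten = [c for c in cycles if c.weight == 10]
        assert len(six) == 2 and len(ten) == 1
        assert xor_cycles(six[0].edge_bits, six[1].edge_bits) == ten[0].edge_bits

    def test_xor_of_barrelene_rings_gives_third(self, barrelene):
        cycles = enumerate_all_cycles_bruteforce(barrelene)
        assert len(cycles) == 3
        a, b, c = (cy.edge_bits for cy in cycles)
        assert xor_cycles(a, b) == c


class TestMolfile:
    def test_minimal(self):
        g = read_molfile(MINIMAL_MOLFILE)
        assert g.n_vertices == 2
        assert g.edges == ((0, 1),)

    def test_benzene(self):
        g = read_molfile(BENZENE_MOLFILE)
        assert g.n_vertices == 6
        assert all(g.degree(v) == 2 for v in range(6))
        assert g.vertex_labels == ("C",) * 6

    def test_bond_to_atom_zero_rejected(self):
        bad = MINIMAL_MOLFILE.replace("  1  2  1  0", "  0  2  1  0")
        with pytest.raises(MolfileParseError):
            read_molfile(bad)

    def test_duplicate_bond_rejected(self):
        bad = BENZENE_MOLFILE.replace("  6  6  0", "  6  7  0").replace(
            "M  END", "  2  1  1  0\nM  END"
        )
        with pytest.raises(MolfileParseError) as exc:
            read_molfile(bad)
        assert "duplicate" in str(exc.value)

    def test_malformed_counts_line(self):
        with pytest.raises(MolfileParseError):
            read_molfile("x\ny\nz\nnot a counts line\n")

    def test_sdf_iteration(self):
        from conftest import DATA

        records = list(read_sdf((DATA / "fixtures.sdf").read_text()))
        assert [t for t, _ in records] == ["naphthalene", "cyclohexane", "biphenyl"]
        assert records[0][1].n_edges == 11


class TestSmiles:
    rdkit = pytest.importorskip("rdkit")

    def test_cyclopropane(self):
        from ringkit import read_smiles

        g = read_smiles("C1CC1")
        assert (g.n_vertices, g.n_edges) == (3, 3)

    def test_naphthalene(self):
        from ringkit import read_smiles

        g = read_smiles("c1ccc2ccccc2c1")
        assert (g.n_vertices, g.n_edges) == (10, 11)
        assert sum(1 for v in range(10) if g.degree(v) == 3) == 2

    def test_propan2ylbenzene(self):
        from ringkit import read_smiles

        g = read_smiles("CC(C)c1ccccc1")
        assert (g.n_vertices, g.n_edges) == (9, 9)

    def test_bad_smiles(self):
        from ringkit import read_smiles

        with pytest.raises(GraphError):
            read_smiles("not-a-smiles(((")


def test_read_graph_text():
    g = read_graph_text("4 4\n0 1\n1 2\n2 3\n3 0\n")
    assert g.n_vertices == 4
    assert circuit_rank(g) == 1
    with pytest.raises(GraphError):
        read_graph_text("4 2\n0 1\n")
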