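"""Minimum cycle basis, relevant/essential cycles and the short cycle sets."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringkit import (
    RelevantCountError,
    build_graph,
    circuit_rank,
    count_relevant,
    edge_short_cycles,
    essential_cycles,
    minimum_cycle_basis,
    relevant_cycles,
    triplet_cycles,
    vertex_short_cycles,
)
from ringkit.fixtures import named_fixture
from ringkit.oracles import (
    enumerate_all_cycles_bruteforce,
    essential_cycles_bruteforce,
    random_connected_graph,
    relevant_cycles_bruteforce,
    shortest_cycles_through_vertex_bruteforce,
    _min_basis_weight,
)
from ringkit.ring_search import fragments, ring_search
from ringkit.short_cycles import InitialCycles, initial_cycles


def nonsimple_fragment(name):
    g = named_fixture(name).graph
    (frag,) = fragments(g, ring_search(g))
    return frag.graph


class TestInitialCycles:
    @pytest.mark.parametrize("name, searches", [("naphthalene", 2), ("anthracene", 4)])
    def test_search_count_restricted_to_branch_vertices(self, name, searches):
        """Fused systems need one search per degree>2 vertex, not per vertex."""
        ic = InitialCycles(nonsimple_fragment(name), only_branch_vertices=True)
        assert ic.search_count == searches

    def test_unrestricted_searches_every_vertex(self):
        ic = InitialCycles(nonsimple_fragment("naphthalene"))
        assert ic.search_count == 10

    def test_families_sorted_by_weight(self):
        fams = initial_cycles(nonsimple_fragment("anthracene"))
        weights = [f.weight for f in fams]
        assert weights == sorted(weights)

    def test_barrelene_families_cover_three_hexagons(self):
        fams = initial_cycles(nonsimple_fragment("barrelene"))
        protos = {f.prototype.edge_bits for f in fams if f.weight == 6}
        assert len(protos) == 3

    def test_member_count_is_path_product(self):
        for fam in initial_cycles(nonsimple_fragment("anthracene")):
            members = list(fam.members(nonsimple_fragment("anthracene")))
            assert len(members) == fam.member_count
            assert all(m.weight == fam.weight for m in members)


class TestMinimumCycleBasis:
    def test_barrelene_two_hexagons(self):
        basis = minimum_cycle_basis(named_fixture("barrelene").graph)
        assert len(basis.cycles) == 2
        assert basis.total_weight == 12
        assert basis.complete

    def test_naphthalene(self):
        basis = minimum_cycle_basis(named_fixture("naphthalene").graph)
        assert [c.weight for c in basis.cycles] == [6, 6]

    def test_acyclic_graph_empty_basis(self):
        g = build_graph(4, [(0, 1), (1, 2), (2, 3)])
        basis = minimum_cycle_basis(g)
        assert basis.cycles == ()
        assert basis.complete

    def test_size_equals_circuit_rank(self, fixture_molecule):
        g = fixture_molecule.graph
        assert len(minimum_cycle_basis(g).cycles) == circuit_rank(g)

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_weight_matches_bruteforce_minimum(self, seed):
        g = random_connected_graph(4 + seed % 9, seed % 6, seed)
        basis = minimum_cycle_basis(g)
        rank = circuit_rank(g)
        assert len(basis.cycles) == rank
        cycles = enumerate_all_cycles_bruteforce(g)
        assert basis.total_weight == _min_basis_weight(cycles, rank)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_independence_shortcut_changes_nothing(self, seed):
        g = random_connected_graph(4 + seed % 8, seed % 5, seed)
        with_shortcut = minimum_cycle_basis(g, use_shortcut=True)
        without = minimum_cycle_basis(g, use_shortcut=False)
        assert with_shortcut.total_weight == without.total_weight
        assert len(with_shortcut.cycles) == len(without.cycles)


class TestRelevantEssential:
    @pytest.mark.parametrize(
        "name, n_relevant, n_essential",
        [
            ("barrelene", 3, 0),
            ("naphthalene", 2, 2),
            ("cubane", 6, 0),
            ("cyclohexane", 1, 1),
            ("anthracene", 3, 3),
            ("azulene", 2, 2),
        ],
    )
    def test_named_structures(self, name, n_relevant, n_essential):
        g = named_fixture(name).graph
        rel = relevant_cycles(g)
        ess = essential_cycles(g)
        assert len(rel) == n_relevant
        assert len(ess) == n_essential
        assert ess.edge_sets() <= rel.edge_sets()

    def test_unique_mcb_implies_equality(self):
        g = named_fixture("naphthalene").graph
        mcb = {c.edge_bits for c in minimum_cycle_basis(g).cycles}
        assert relevant_cycles(g).edge_sets() == mcb
        assert essential_cycles(g).edge_sets() == mcb

    def test_count_without_enumeration(self):
        assert count_relevant(named_fixture("barrelene").graph) == 3
        assert count_relevant(named_fixture("naphthalene").graph) == 2
        assert count_relevant(build_graph(3, [(0, 1), (1, 2)])) == 0

    def test_count_guard(self):
        g = named_fixture("barrelene").graph
        with pytest.raises(RelevantCountError) as exc:
            relevant_cycles(g, limit=2)
        assert exc.value.count == 3

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_union_and_intersection_of_all_mcbs(self, seed):
        g = random_connected_graph(4 + seed % 7, seed % 5, seed)
        try:
            rel_oracle = relevant_cycles_bruteforce(g, max_rank=5)
            ess_oracle = essential_cycles_bruteforce(g, max_rank=5)
        except ValueError:
            return  # oracle guard tripped; graph too cyclic for brute force
        assert relevant_cycles(g).edge_sets() == rel_oracle
        assert essential_cycles(g).edge_sets() == ess_oracle
        assert count_relevant(g) == len(rel_oracle)


class TestVertexEdgeShort:
    @pytest.mark.parametrize(
        "name, expected",
        [("cyclohexane", 1), ("naphthalene", 2), ("barrelene", 3)],
    )
    def test_vertex_short_counts(self, name, expected):
        assert len(vertex_short_cycles(named_fixture(name).graph)) == expected

    @pytest.mark.parametrize(
        "name, expected",
        [("cyclohexane", 1), ("naphthalene", 2), ("azulene", 2)],
    )
    def test_edge_short_counts(self, name, expected):
        assert len(edge_short_cycles(named_fixture(name).graph)) == expected

    def test_azulene_lssr_is_five_and_seven_ring(self):
        g = named_fixture("azulene").graph
        assert sorted(edge_short_cycles(g).weights()) == [5, 7]

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_vertex_short_is_bfs_minimum(self, seed):
        g = random_connected_graph(4 + seed % 7, seed % 5, seed)
        expected = set()
        for v in range(g.n_vertices):
            expected |= shortest_cycles_through_vertex_bruteforce(g, v)
        assert vertex_short_cycles(g).edge_sets() == expected

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_edge_short_is_minimal_through_each_edge(self, seed):
        g = random_connected_graph(4 + seed % 7, seed % 5, seed)
        cycles = enumerate_all_cycles_bruteforce(g)
        expected = set()
        for ei in range(g.n_edges):
            through = [c for c in cycles if ei in c.edge_bits]
            if through:
                w = min(c.weight for c in through)
                expected |= {c.edge_bits for c in through if c.weight == w}
        assert edge_short_cycles(g).edge_sets() == expected


class TestTripletCycles:
    def test_naphthalene_contains_envelope(self):
        result = triplet_cycles(named_fixture("naphthalene").graph)
        assert 10 in result.weights()

    def test_anthracene_avoids_perimeter(self):
        result = triplet_cycles(named_fixture("anthracene").graph)
        weights = sorted(result.weights())
        assert weights.count(10) == 2
        assert 14 not in weights

    def test_cyclohexane_unique_vs_nonunique(self):
        g = named_fixture("cyclohexane").graph
        assert len(triplet_cycles(g, unique=True)) == 1
        assert len(triplet_cycles(g, unique=False)) == 6  # one per triple

    def test_each_triplet_cycle_is_shortest_for_its_triple(self):
        g = named_fixture("azulene").graph
        cycles = enumerate_all_cycles_bruteforce(g)
        for cyc in triplet_cycles(g).cycles:
            verts = cyc.vertices()
            for i in range(len(verts)):
                u, v, w = verts[i - 1], verts[i], verts[(i + 1) % len(verts)]
                through = [
                    c
                    for c in cycles
                    if {u, v, w} <= set(c.vertices())
                    and c.edge_bits.bits >> g.edge_index(u, v) & 1
                    and c.edge_bits.bits >> g.edge_index(v, w) & 1
                ]
                assert min(c.weight for c in through) <= cyc.weight
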