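import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyforge.errors import InputError
from polyforge.residue_graphs import graph_from_topology, parse_sequence
from polyforge.topology_gen import (
    Link,
    apply_link,
    build_disconnected,
    gen_params,
    match_link,
)

from .conftest import cycle_graph, path_graph, star_graph
from .oracles import brute_force_matches


def bond_link(resname="B"):
    pattern = nx.Graph()
    pattern.add_node(0, resname=resname)
    pattern.add_node(1, resname=resname)
    pattern.add_edge(0, 1)
    from polyforge.topology_gen import Interaction

    return Link(pattern=pattern,
                interactions={"bonds": [Interaction(((0, "B1"), (1, "B1")),
                                                    1, (0.47, 1250.0))]},
                name="bond")


class TestBuildDisconnected:
    def test_counts_single_atom_blocks(self, bead_spring):
        mol = build_disconnected(path_graph(3), bead_spring)
        assert len(mol.atoms) == 3
        assert mol.graph.number_of_edges() == 0

    def test_vinyl_two_residues(self, vinyl3):
        mol = build_disconnected(path_graph(2, "VNL"), vinyl3)
        assert len(mol.atoms) == 6
        assert len(mol.interactions["bonds"]) == 4
        cross = [1 for a, b in mol.graph.edges
                 if mol.residue_of(a) != mol.residue_of(b)]
        assert not cross

    def test_missing_block_names_resname_and_node(self, bead_spring):
        with pytest.raises(InputError, match="'X'.*node 1|node 1.*'X'"):
            g = path_graph(2)
            g.nodes[1]["resname"] = "X"
            build_disconnected(g, bead_spring)


class TestMatchLink:
    def test_path_of_three_has_two_bond_sites(self):
        matches = match_link(path_graph(3), bond_link())
        assert matches == [{0: 0, 1: 1}, {0: 1, 1: 2}]

    def test_cycle_of_three_has_three_bond_sites(self):
        assert len(match_link(cycle_graph(3), bond_link())) == 3

    def test_wrong_resname_matches_nothing(self):
        assert match_link(path_graph(4), bond_link(resname="X")) == []

    def test_wildcard_matches_mixed_resnames(self):
        g = parse_sequence("PS:2|PEO:2")
        matches = match_link(g, bond_link(resname="*"))
        assert len(matches) == 3

    def test_edge_attribute_constraint(self):
        g = path_graph(3)
        g.edges[0, 1]["linktype"] = "main"
        g.edges[1, 2]["linktype"] = "branch"
        link = bond_link()
        link.pattern.edges[0, 1]["linktype"] = "branch"
        assert match_link(g, link) == [{0: 1, 1: 2}]


class TestMatchOracle:
    """match_link must agree with exhaustive injective enumeration."""

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_graphs_and_patterns(self, data):
        n = data.draw(st.integers(2, 8), label="graph size")
        p_edge = data.draw(st.floats(0.2, 0.9), label="edge density")
        seed = data.draw(st.integers(0, 10_000), label="seed")
        rng = np.random.default_rng(seed)
        graph = nx.gnp_random_graph(n, p_edge, seed=seed)
        names = ["A", "B"]
        for node in graph.nodes:
            graph.nodes[node]["resname"] = names[rng.integers(0, 2)]
        k = data.draw(st.integers(1, min(4, n)), label="pattern size")
        pattern = nx.path_graph(k)
        mapping = {i: i - k // 2 for i in range(k)}
        pattern = nx.relabel_nodes(pattern, mapping)
        for node in pattern.nodes:
            pattern.nodes[node]["resname"] = \
                data.draw(st.sampled_from(["A", "B", "*"]),
                          label=f"resname {node}")
        link = Link(pattern=pattern, name="random")
        assert match_link(graph, link) == brute_force_matches(graph, link)


class TestApplyLink:
    def test_bond_between_first_residues(self, bead_spring):
        mol = build_disconnected(path_graph(5), bead_spring)
        apply_link(mol, bond_link(), {0: 0, 1: 1})
        assert len(mol.interactions["bonds"]) == 1
        assert mol.interactions["bonds"][0].atoms == (0, 1)
        assert mol.graph.has_edge(0, 1)

    def test_angle_link_resolves_global_indices(self, bead_spring):
        mol = build_disconnected(path_graph(5), bead_spring)
        angle = bead_spring.links[1]
        apply_link(mol, angle, {-1: 1, 0: 2, 1: 3})
        (term,) = mol.interactions["angles"]
        assert term.atoms == (1, 2, 3)

    def test_unknown_atom_name_reports_residue(self, bead_spring):
        mol = build_disconnected(path_graph(2), bead_spring)
        link = bond_link()
        from polyforge.topology_gen import Interaction

        link.interactions = {"bonds": [Interaction(((0, "CX"), (1, "B1")),
                                                   1, ())]}
        with pytest.raises(InputError, match="CX"):
            apply_link(mol, link, {0: 0, 1: 1})

    def test_later_link_replaces_same_tuple(self, bead_spring):
        from polyforge.topology_gen import Interaction

        mol = build_disconnected(path_graph(2), bead_spring)
        apply_link(mol, bond_link(), {0: 0, 1: 1})
        override = bond_link()
        override.interactions = {"bonds": [Interaction(((0, "B1"), (1, "B1")),
                                                       1, (0.5, 999.0))]}
        apply_link(mol, override, {0: 0, 1: 1})
        assert len(mol.interactions["bonds"]) == 1
        assert mol.interactions["bonds"][0].params == (0.5, 999.0)


class TestGenParams:
    def test_path_combinatorics(self, bead_spring):
        mol = gen_params(parse_sequence("B:5"), bead_spring)
        assert len(mol.atoms) == 5
        assert len(mol.interactions["bonds"]) == 4
        assert len(mol.interactions["angles"]) == 3
        assert nx.is_connected(mol.graph)

    def test_cycle_combinatorics(self, bead_spring):
        mol = gen_params(cycle_graph(5), bead_spring)
        assert len(mol.interactions["bonds"]) == 5
        assert len(mol.interactions["angles"]) == 5

    def test_star_connects_all_arms(self, bead_spring):
        mol = gen_params(star_graph(3), bead_spring)
        assert len(mol.interactions["bonds"]) == 3
        assert nx.is_connected(mol.graph)

    def test_atom_count_conserved_by_links(self, bead_spring):
        g = path_graph(7)
        disconnected = build_disconnected(g, bead_spring)
        full = gen_params(g, bead_spring)
        assert len(full.atoms) == len(disconnected.atoms)
        assert [a.name for a in full.atoms] == \
            [a.name for a in disconnected.atoms]

    @pytest.mark.parametrize("sequence", ["B:2", "B:9"])
    def test_graph_round_trip_linear(self, bead_spring, sequence):
        g = parse_sequence(sequence)
        mol = gen_params(g, bead_spring)
        assert nx.is_isomorphic(graph_from_topology(mol), g)

    def test_graph_round_trip_branched(self, bead_spring):
        from polyforge.residue_graphs import random_branched_graph

        g = random_branched_graph(15, 0.4, 3, resname="B", seed=4)
        mol = gen_params(g, bead_spring)
        assert nx.is_isomorphic(graph_from_topology(mol), g)

    def test_idempotent_for_fixed_inputs(self, vinyl3):
        a = gen_params(parse_sequence("VNL:4"), vinyl3)
        b = gen_params(parse_sequence("VNL:4"), vinyl3)
        assert a == b
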