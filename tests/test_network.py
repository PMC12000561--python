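"""Node assignment, contact persistence, betweenness and optimal paths."""

import math

import numpy as np
import pandas as pd
import pytest

from allodyn.dynamics import CorrelationMatrix
from allodyn.errors import IntegrityError, NodeAssignmentError
from allodyn.io import Atom, Topology, Trajectory
from allodyn.network import (
    DynamicNetwork,
    Node,
    NodeSet,
    assign_nodes,
    build_network,
    contact_map,
    edge_betweenness,
    optimal_path,
)
from allodyn.synth import build_covariance, CovarianceSpec, sample_trajectory

from conftest import CHAIN, CHAIN_CONTACTS, DECOY_CONTACTS
from oracles import enumerate_edge_betweenness, enumerate_optimal_paths


def network_from_edges(edges: dict, n_nodes: int | None = None) -> DynamicNetwork:
    """Build a DynamicNetwork directly from {frozenset((i, j)): weight}."""
    n = n_nodes or max(max(e) for e in edges) + 1
    nodes = NodeSet(nodes=[
        Node(i, f"n{i}", i, frozenset({i}), ("A", i + 1), "protein")
        for i in range(n)
    ])
    rows, c = [], np.eye(n)
    for e, w in edges.items():
        i, j = sorted(e)
        rows.append((i, j, 1.0, True, True))
        c[i, j] = c[j, i] = math.exp(-w)
    contacts = pd.DataFrame(
        rows, columns=["i", "j", "contact_fraction", "eligible",
                       "eligible_edge"])
    # non-adjacent labels so no pair is filtered as a sequence neighbour
    nodes = NodeSet(nodes=[
        Node(i, f"n{i}", i, frozenset({i}), ("A", 2 * i + 1), "protein")
        for i in range(n)
    ])
    corr = CorrelationMatrix(matrix=c, labels=[f"n{i}" for i in range(n)])
    return build_network(contacts, corr, nodes)


class TestAssignNodes:
    def test_node_counting(self, toy, toy_nodes):
        # 10 amino acids + 4 nucleotides x 2 + 1 cofactor = 19
        assert len(toy_nodes) == 19
        kinds = [n.kind for n in toy_nodes.nodes]
        assert kinds.count("protein") == 10
        assert kinds.count("backbone") == 4
        assert kinds.count("base") == 4
        assert kinds.count("cofactor") == 1

    def test_missing_ca_names_residue(self, toy):
        topology, _ = toy
        atoms = [a for a in topology.atoms
                 if not (a.residue_key == ("A", 3) and a.atom_name == "CA")]
        from dataclasses import replace
        atoms = [replace(a, atom_index=i) for i, a in enumerate(atoms)]
        broken = Topology(atoms=atoms, bonds=set())
        with pytest.raises(NodeAssignmentError, match="A/3"):
            assign_nodes(broken)

    def test_nucleotide_groups_partition_heavy_atoms(self, toy, toy_nodes):
        topology, _ = toy
        for key in {n.residue_key for n in toy_nodes.nodes if n.kind == "base"}:
            heavy = {a.atom_index for a in topology.atoms
                     if a.residue_key == key}
            groups = [n.node_group for n in toy_nodes.nodes
                      if n.residue_key == key]
            assert len(groups) == 2
            assert groups[0] & groups[1] == frozenset()
            assert groups[0] | groups[1] == heavy

    def test_abasic_base_node_flagged(self, chain_toy):
        topology, reference = chain_toy
        nodes = assign_nodes(topology, reference)
        ap = nodes.by_label("B:2:DT:base")
        assert "abasic" in ap.flags
        assert topology.atoms[ap.anchor_atom_index].atom_name == "C1'"


class TestContactMap:
    @pytest.mark.parametrize("fraction,expected_edge", [
        (0.74, False), (0.75, False), (0.76, True),
    ])
    def test_strict_persistence_boundary(self, fraction, expected_edge, toy):
        topology, reference = toy
        nodes = assign_nodes(topology, reference)
        pair = ("A:2:GLY", "A:6:LEU")
        cov = build_covariance(CovarianceSpec(n_nodes=len(nodes)))
        traj = sample_trajectory(topology, reference, cov, 100,
                                 contact_schedule={pair: fraction}, seed=21)
        contacts = contact_map(traj, topology, nodes)
        i = nodes.by_label(pair[0]).node_id
        j = nodes.by_label(pair[1]).node_id
        row = contacts[(contacts.i == min(i, j)) & (contacts.j == max(i, j))]
        assert float(row.contact_fraction.iloc[0]) == pytest.approx(fraction)
        assert bool(row.eligible_edge.iloc[0]) is expected_edge

    def test_always_in_contact(self, chain_toy):
        topology, reference = chain_toy
        nodes = assign_nodes(topology, reference)
        traj = Trajectory(np.repeat(reference[None], 3, axis=0))
        contacts = contact_map(traj, topology, nodes)
        for a, b in CHAIN_CONTACTS:
            i, j = sorted((nodes.by_label(a).node_id, nodes.by_label(b).node_id))
            row = contacts[(contacts.i == i) & (contacts.j == j)]
            assert float(row.contact_fraction.iloc[0]) == 1.0

    def test_sequence_neighbours_ineligible(self, toy):
        topology, reference = toy
        nodes = assign_nodes(topology, reference)
        traj = Trajectory(reference[None])
        contacts = contact_map(traj, topology, nodes)
        i, j = nodes.by_label("A:1:ALA").node_id, nodes.by_label("A:2:GLY").node_id
        row = contacts[(contacts.i == min(i, j)) & (contacts.j == max(i, j))]
        assert not bool(row.eligible.iloc[0])

    def test_monotone_in_cutoff_and_persistence(self, chain_toy):
        topology, reference = chain_toy
        nodes = assign_nodes(topology, reference)
        cov = build_covariance(CovarianceSpec(n_nodes=len(nodes)))
        traj = sample_trajectory(topology, reference, cov, 50,
                                 contact_schedule={CHAIN_CONTACTS[0]: 0.8},
                                 seed=3)
        lo = contact_map(traj, topology, nodes, cutoff=4.5)
        hi = contact_map(traj, topology, nodes, cutoff=6.0)
        assert np.all(hi.contact_fraction >= lo.contact_fraction)
        tight = contact_map(traj, topology, nodes, persistence=0.9)
        assert set(map(tuple, tight[tight.eligible_edge][["i", "j"]].values)) <= \
            set(map(tuple, lo[lo.eligible_edge][["i", "j"]].values))


class TestBuildNetwork:
    def test_weight_closed_forms(self):
        net = network_from_edges({frozenset((0, 1)): 0.0,
                                  frozenset((1, 2)): 1.0})
        assert net.graph[0][1]["weight"] == pytest.approx(0.0, abs=1e-12)
        assert net.graph[1][2]["weight"] == pytest.approx(1.0, abs=1e-12)
        assert net.graph[1][2]["correlation"] == pytest.approx(math.exp(-1))

    def test_below_floor_dropped(self):
        n = 3
        nodes = NodeSet(nodes=[
            Node(i, f"n{i}", i, frozenset({i}), ("A", 2 * i + 1), "protein")
            for i in range(n)])
        c = np.eye(n)
        c[0, 1] = c[1, 0] = 1e-9
        contacts = pd.DataFrame([(0, 1, 1.0, True, True)],
                                columns=["i", "j", "contact_fraction",
                                         "eligible", "eligible_edge"])
        corr = CorrelationMatrix(matrix=c, labels=[f"n{i}" for i in range(n)])
        net = build_network(contacts, corr, nodes)
        assert net.graph.number_of_edges() == 0


class TestBetweennessAndPaths:
    def test_path_graph_counts(self):
        net = network_from_edges({frozenset((0, 1)): 1.0,
                                  frozenset((1, 2)): 1.0})
        bc = edge_betweenness(net).set_index(["node_i", "node_j"])["betweenness"]
        assert bc[("n0", "n1")] == pytest.approx(2.0)
        assert bc[("n1", "n2")] == pytest.approx(2.0)

    def test_triangle_counts(self):
        net = network_from_edges({frozenset((0, 1)): 1.0,
                                  frozenset((1, 2)): 1.0,
                                  frozenset((0, 2)): 1.0})
        bc = edge_betweenness(net)
        assert np.allclose(bc["betweenness"], 1.0)

    def test_disconnected_component(self):
        net = network_from_edges({frozenset((0, 1)): 0.7})
        net.graph.add_node(2)
        bc = edge_betweenness(net)
        assert float(bc["betweenness"].iloc[0]) == pytest.approx(1.0)

    def test_single_edge_path(self):
        net = network_from_edges({frozenset((0, 1)): 0.4})
        res = optimal_path(net, "n0", "n1")
        assert res.nodes == ["n0", "n1"]
        assert res.total_weight == pytest.approx(0.4)

    def test_two_routes_cheaper_wins(self):
        net = network_from_edges({
            frozenset((0, 1)): 1.0, frozenset((1, 3)): 0.5,   # total 1.5
            frozenset((0, 2)): 1.0, frozenset((2, 3)): 1.0,   # total 2.0
        })
        res = optimal_path(net, "n0", "n3")
        assert res.nodes == ["n0", "n1", "n3"]
        assert res.total_weight == pytest.approx(1.5)

    def test_unreachable_is_explicit(self):
        net = network_from_edges({frozenset((0, 1)): 0.4}, n_nodes=3)
        res = optimal_path(net, "n0", "n2")
        assert not res.found and res.nodes == []

    def test_tie_break_is_lexicographic(self):
        net = network_from_edges({
            frozenset((0, 1)): 1.0, frozenset((1, 3)): 1.0,
            frozenset((0, 2)): 1.0, frozenset((2, 3)): 1.0,
        })
        res = optimal_path(net, "n0", "n3")
        assert res.nodes == ["n0", "n1", "n3"]

    @pytest.mark.parametrize("seed", range(25))
    def test_random_graphs_match_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 8))
        edges = {}
        weight_pool = [0.5, 1.0, 1.0, 1.5, 2.0]  # repeats force tie cases
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.55:
                    edges[frozenset((i, j))] = float(rng.choice(weight_pool))
        if not edges:
            edges[frozenset((0, 1))] = 1.0
        net = network_from_edges(edges)
        bc = edge_betweenness(net)
        oracle = enumerate_edge_betweenness(edges, range(n))
        got = {(r.node_i, r.node_j): r.betweenness for r in bc.itertuples()}
        for e, val in oracle.items():
            i, j = sorted(e)
            assert got[(f"n{i}", f"n{j}")] == pytest.approx(val, abs=1e-9)
        # optimal path against enumeration for one pair
        src, tgt = 0, n - 1
        opt, best = enumerate_optimal_paths(edges, src, tgt)
        res = optimal_path(net, f"n{src}", f"n{tgt}")
        if not opt:
            assert not res.found
        else:
            assert res.total_weight == pytest.approx(best, abs=1e-9)
            ids = [int(l[1:]) for l in res.nodes]
            assert ids in opt
            assert ids == min(opt)

    def test_planted_chain_recovered(self, chain_toy):
        topology, reference = chain_toy
        nodes = assign_nodes(topology, reference)
        labels = nodes.labels()
        idx = tuple(labels.index(l) for l in CHAIN)
        cov = build_covariance(CovarianceSpec(
            n_nodes=len(nodes), background=0.2, planted_path=idx,
            planted_correlation=0.9))
        schedule = {p: 1.0 for p in CHAIN_CONTACTS + DECOY_CONTACTS}
        traj = sample_trajectory(topology, reference, cov, 2000,
                                 contact_schedule=schedule, seed=77)
        from allodyn.dynamics import correlation_matrix
        corr = correlation_matrix(traj, nodes)
        contacts = contact_map(traj, topology, nodes)
        net = build_network(contacts, corr, nodes)
        res = optimal_path(net, CHAIN[0], CHAIN[-1])
        assert res.nodes == CHAIN

    def test_relabelled_network_is_isomorphic(self):
        edges = {frozenset((0, 1)): 0.3, frozenset((1, 2)): 0.6,
                 frozenset((0, 3)): 1.1}
        net = network_from_edges(edges)
        perm = {0: 2, 1: 0, 2: 3, 3: 1}
        permuted = {frozenset((perm[min(e)], perm[max(e)])): w
                    for e, w in edges.items()}
        net2 = network_from_edges(permuted)
        ew1 = sorted(d["weight"] for _, _, d in net.graph.edges(data=True))
        ew2 = sorted(d["weight"] for _, _, d in net2.graph.edges(data=True))
        assert np.allclose(ew1, ew2)
        import networkx as nx
        assert nx.is_isomorphic(net.graph, net2.graph)

    def test_correlation_above_one_rejected(self):
        nodes = NodeSet(nodes=[
            Node(i, f"n{i}", i, frozenset({i}), ("A", 2 * i + 1), "protein")
            for i in range(2)])
        contacts = pd.DataFrame([(0, 1, 1.0, True, True)],
                                columns=["i", "j", "contact_fraction",
                                         "eligible", "eligible_edge"])
        with pytest.raises(IntegrityError):
            CorrelationMatrix(matrix=np.array([[1.0, 1.5], [1.5, 1.0]]),
                              labels=["n0", "n1"])
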