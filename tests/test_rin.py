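"""Residue interaction networks: construction, stats, centrality,
communities and pathways — with naive brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rindyn.covariance import DCCMMatrix
from rindyn.rin import (
    annotate_strengths,
    build_rin,
    centralities,
    girvan_newman,
    interface_pathway,
    topology_stats,
)
from rindyn.structure import Atom, Residue, Topology
from rindyn.synth import ToyComplexSpec, gen_toy_complex


# ---------------------------------------------------------------------------
# naive oracles (independent of networkx)
# ---------------------------------------------------------------------------

def naive_all_shortest_paths(graph):
    """Floyd-Warshall by hand: dist dict and path counts via enumeration."""
    nodes = list(graph.nodes)
    inf = float("inf")
    dist = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    for u, v in graph.edges:
        dist[u][v] = dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def naive_betweenness(graph):
    """Enumerate all simple shortest paths per pair (small graphs only)."""
    nodes = list(graph.nodes)
    dist = naive_all_shortest_paths(graph)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if dist[s][t] == float("inf"):
            continue
        paths = [p for p in nx.all_simple_paths(graph, s, t, cutoff=dist[s][t])
                 if len(p) - 1 == dist[s][t]]
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p[1:-1])
            if paths:
                score[v] += on / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: score[v] / norm for v in nodes}


def naive_closeness(graph, dist=None):
    dist = dist or naive_all_shortest_paths(graph)
    out = {}
    for u in graph.nodes:
        finite = [d for v, d in dist[u].items() if v != u and d != float("inf")]
        out[u] = len(finite) / sum(finite) if finite and sum(finite) else 0.0
    return out


def bead_topology(positions_by_residue):
    """[(chain, seq, xyz)] -> (Topology, frame)."""
    atoms, residues, coords = [], [], []
    for chain, seq, xyz in positions_by_residue:
        ridx = len(residues)
        residues.append(Residue("GLY", seq, chain, [len(atoms)]))
        atoms.append(Atom("CA", "C", ridx))
        coords.append(xyz)
    return Topology(atoms, residues), np.asarray(coords, float)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildRin:
    def test_distant_residues_no_edge(self):
        top, frame = bead_topology([("A", 1, (0, 0, 0)), ("A", 5, (2, 0, 0))])
        g = build_rin(frame, top)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_covalent_exclusion_in_tripeptide(self, helix12):
        # consecutive residues are peptide-bonded: no i,i+1 edges at all
        top, traj = helix12
        from rindyn.structure import perceive_bonds
        top.bonds = perceive_bonds(top, traj.frame(0))
        g = build_rin(traj.frame(0), top)
        seq = {g.nodes[n]["seq_id"]: n for n in g.nodes}
        for s in range(1, 12):
            assert not g.has_edge(seq[s], seq[s + 1])
        # i,i+2 contacts in a tight helix do survive
        assert any(g.has_edge(seq[s], seq[s + 2]) for s in range(1, 11))

    def test_matches_bruteforce_heavy_atom_scan(self, two_chain_bridge):
        top, traj = two_chain_bridge
        frame = traj.frame(0)
        g = build_rin(frame, top)
        heavy = [i for i, a in enumerate(top.atoms) if a.is_heavy]
        expected = set()
        for i, j in itertools.combinations(heavy, 2):
            ri, rj = top.atoms[i].residue_index, top.atoms[j].residue_index
            if ri == rj:
                continue
            if np.linalg.norm(frame[i] - frame[j]) < 0.5:
                a, b = top.residues[ri], top.residues[rj]
                expected.add(frozenset((f"{a.chain_id}:{a.seq_id}",
                                        f"{b.chain_id}:{b.seq_id}")))
        got = {frozenset(e) for e in g.edges}
        assert got == expected

    def test_edge_distances_below_cutoff(self, two_chain_bridge):
        top, traj = two_chain_bridge
        g = build_rin(traj.frame(0), top)
        assert all(d["distance"] < 0.5 for _, _, d in g.edges(data=True))


class TestStrengths:
    def _toy_graph_and_dccm(self, matrix):
        n = matrix.shape[0]
        top, frame = bead_topology(
            [("A", i + 1, (0.45 * i, 0, 0)) for i in range(n)])
        g = build_rin(frame, top)  # chain of consecutive contacts
        d = DCCMMatrix(matrix=matrix, selection=np.arange(n))
        return top, g, d

    def test_all_ones_weighted_degree_equals_degree(self):
        top, g, d = self._toy_graph_and_dccm(np.ones((6, 6)))
        annotate_strengths(g, d, top)
        for node in g.nodes:
            assert g.nodes[node]["weighted_degree"] == g.degree[node]

    def test_identity_dccm_zero_strengths(self):
        top, g, d = self._toy_graph_and_dccm(np.eye(6))
        annotate_strengths(g, d, top)
        assert all(data["strength"] == 0.0 for _, _, data in g.edges(data=True))

    def test_random_dccm_matches_hand_summation(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-1, 1, (10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        top, g, d = self._toy_graph_and_dccm(m)
        annotate_strengths(g, d, top)
        for node in g.nodes:
            expected = sum(abs(m[g.nodes[node]["residue_index"],
                                g.nodes[nb]["residue_index"]])
                           for nb in g.neighbors(node))
            assert g.nodes[node]["weighted_degree"] == pytest.approx(expected)

    def test_missing_residue_raises(self):
        top, g, _ = self._toy_graph_and_dccm(np.eye(6))
        short = DCCMMatrix(matrix=np.eye(5), selection=np.arange(5))
        with pytest.raises(Exception, match="A:6"):
            annotate_strengths(g, short, top)


# ---------------------------------------------------------------------------
# statistics / centralities
# ---------------------------------------------------------------------------

class TestTopologyStats:
    def test_complete_graph_closed_forms(self):
        stats = topology_stats(nx.complete_graph(5))
        assert stats.clustering_coefficient == pytest.approx(1.0)
        assert stats.characteristic_path_length == pytest.approx(1.0)
        assert stats.diameter == 1
        assert stats.density == pytest.approx(1.0)
        assert stats.avg_neighbors == pytest.approx(4.0)

    def test_path_graph_hand_enumeration(self):
        stats = topology_stats(nx.path_graph(5))
        assert stats.characteristic_path_length == pytest.approx(2.0)
        assert stats.diameter == 4
        assert stats.radius == 2
        assert stats.n_components == 1
        assert stats.avg_neighbors == pytest.approx(2 * 4 / 5)

    def test_erdos_renyi_against_bruteforce(self):
        g = nx.gnp_random_graph(30, 0.15, seed=42)
        stats = topology_stats(g)
        dist = naive_all_shortest_paths(g)
        finite = [dist[u][v] for u in g for v in g
                  if u != v and dist[u][v] != float("inf")]
        assert stats.characteristic_path_length == pytest.approx(
            sum(finite) / len(finite))
        ecc = [max(d for v, d in dist[u].items() if d != float("inf"))
               for u in g]
        assert stats.diameter == max(ecc)
        assert stats.radius == min(ecc)
        degrees = np.array([g.degree[u] for u in g], float)
        n = g.number_of_nodes()
        assert stats.density == pytest.approx(
            2 * g.number_of_edges() / (n * (n - 1)))
        assert stats.heterogeneity == pytest.approx(
            degrees.std() / degrees.mean())
        assert stats.centralization == pytest.approx(
            (n / (n - 2)) * (degrees.max() / (n - 1) - stats.density))
        assert stats.avg_neighbors == pytest.approx(degrees.mean())
        assert stats.n_components == nx.number_connected_components(g)


class TestCentralities:
    def test_star_center_betweenness_one(self):
        g = nx.star_graph(5)  # center 0 + 5 leaves
        profile = centralities(g)
        assert profile.betweenness[0] == pytest.approx(1.0)
        assert all(profile.betweenness[v] == 0.0 for v in range(1, 6))

    def test_cycle_symmetry(self):
        profile = centralities(nx.cycle_graph(5))
        values = list(profile.betweenness.values())
        assert np.ptp(values) < 1e-12

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_naive_enumeration(self, seed):
        g = nx.gnp_random_graph(20, 0.2, seed=seed)
        profile = centralities(g)
        nb = naive_betweenness(g)
        ncl = naive_closeness(g)
        for v in g.nodes:
            assert profile.betweenness[v] == pytest.approx(nb[v], abs=1e-10)
            assert profile.closeness[v] == pytest.approx(ncl[v], abs=1e-10)
            assert 0.0 <= profile.betweenness[v] <= 1.0
            assert 0.0 <= profile.closeness[v] <= 1.0


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

class TestGirvanNewman:
    def test_two_cliques_one_bridge(self):
        g = nx.Graph()
        for base in (0, 6):
            for i, j in itertools.combinations(range(base, base + 6), 2):
                g.add_edge(i, j)
        g.add_edge(0, 6)
        partition = girvan_newman(g)
        assert partition.n_communities == 2
        comms = {frozenset(c) for c in partition.communities()}
        assert comms == {frozenset(range(6)), frozenset(range(6, 12))}
        assert partition.n_integrated == 2 and partition.n_isolated == 0

    def test_edgeless_graph_every_node_isolated(self):
        g = nx.empty_graph(7)
        partition = girvan_newman(g)
        assert partition.n_communities == 7
        assert partition.n_isolated == 7

    def test_complete_graph_single_community(self):
        partition = girvan_newman(nx.complete_graph(6))
        assert partition.n_communities == 1
        assert partition.n_integrated == 1

    def test_toy_complex_cluster_layout(self):
        spec = ToyComplexSpec(chain_sizes=(6, 6), bridges=[((0, 1), (1, 1))],
                              layout="cluster")
        top, traj = gen_toy_complex(spec)
        g = build_rin(traj.frame(0), top)
        partition = girvan_newman(g)
        assert partition.n_communities == 2


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

class TestInterfacePathway:
    def test_unique_bridge_identified(self, two_chain_bridge):
        top, traj = two_chain_bridge
        g = build_rin(traj.frame(0), top)
        pw = interface_pathway(g, "A:1", "B")
        assert not pw.terminated
        assert pw.bridging_pairs == {frozenset(("A:10", "B:10"))}
        # every path into chain B passes the bridge
        assert "A:10" in pw.nodes and "B:10" in pw.nodes

    def test_no_interchain_edges_terminates(self):
        top, traj = gen_toy_complex(ToyComplexSpec(chain_sizes=(6, 6),
                                                   bridges=[]))
        g = build_rin(traj.frame(0), top)
        pw = interface_pathway(g, "A:1", "B")
        assert pw.terminated
        assert pw.bridging_pairs == set()
        assert all(g.nodes[n]["chain"] == "A" for n in pw.nodes)

    def test_matches_exhaustive_enumeration_on_small_toy(self):
        spec = ToyComplexSpec(chain_sizes=(6, 6), bridges=[((0, 3), (1, 3))])
        top, traj = gen_toy_complex(spec)
        g = build_rin(traj.frame(0), top)
        source = "A:1"
        pw = interface_pathway(g, source, "B")
        dist = naive_all_shortest_paths(g)
        exp_nodes, exp_edges = {source}, set()
        for t in g.nodes:
            if g.nodes[t]["chain"] != "B" or dist[source][t] == float("inf"):
                continue
            for p in nx.all_simple_paths(g, source, t, cutoff=dist[source][t]):
                if len(p) - 1 != dist[source][t]:
                    continue
                exp_nodes.update(p)
                exp_edges.update(frozenset(e) for e in zip(p, p[1:]))
        assert pw.nodes == exp_nodes
        assert pw.edges == exp_edges

    def test_subgraph_minimality(self, two_chain_bridge):
        # every member node lies on at least one shortest source->target path
        top, traj = two_chain_bridge
        g = build_rin(traj.frame(0), top)
        source = "A:1"
        pw = interface_pathway(g, source, "B")
        dist = dict(nx.single_source_shortest_path_length(g, source))
        for node in pw.nodes:
            if node == source:
                continue
            # node is on a shortest path to some target iff some target t has
            # dist(s,t) = dist(s,node) + dist(node,t)
            dn = dict(nx.single_source_shortest_path_length(g, node))
            ok = any(g.nodes[t]["chain"] == "B" and t in dn
                     and dist[node] + dn[t] == dist[t]
                     for t in g.nodes if t in dist)
            assert ok
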