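"""Residue interaction networks: construction, topology statistics,
centralities, communities and inter-chain communication pathways.

A residue interaction network (RIN) has one node per amino-acid residue and
an undirected edge between residues i and j when any heavy atom of i is
closer than 0.5 nm (5 Angstrom, roughly the reach of attractive van der
Waals forces) to any heavy atom of j, provided the residues are not
covalently bonded (peptide-bond neighbours and disulfide partners carry no
edge).  Edges may be annotated with a strength |C_ij| taken from a DCCM,
giving each node a correlation-weighted degree (the sum of incident
strengths).

Shortest paths are unweighted hop counts (an inverse-strength weighted mode
is available but non-default); communities come from iterative removal of
the highest-betweenness edge (Girvan-Newman), stopping at maximal
modularity by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .covariance import DCCMMatrix
from .errors import AnalysisError
from .structure import Topology, perceive_bonds

__all__ = [
    "TopologyStats",
    "CentralityProfile",
    "CommunityPartition",
    "PathwaySubgraph",
    "build_rin",
    "annotate_strengths",
    "topology_stats",
    "centralities",
    "girvan_newman",
    "interface_pathway",
    "node_key",
]


def node_key(chain_id: str, seq_id: int, insertion_code: str = "") -> str:
    """Canonical RIN node label, e.g. ``"A:299"``."""
    return f"{chain_id}:{seq_id}{insertion_code}"


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_rin(frame: np.ndarray, topology: Topology, cutoff: float = 0.5,
              include_hetero: bool = False) -> nx.Graph:
    """Build the residue interaction network from one coordinate frame.

    Nodes are standard amino-acid residues (plus hetero groups when
    ``include_hetero``); an edge appears when any heavy-atom pair of two
    residues is strictly closer than ``cutoff`` nm and the residues are not
    covalently bonded.  The minimum heavy-atom distance is stored on each
    edge as ``distance``.
    """
    from scipy.spatial import cKDTree

    frame = np.asarray(frame, dtype=float)
    residues = [(ridx, res) for ridx, res in enumerate(topology.residues)
                if res.is_protein or (include_hetero and res.is_hetero
                                      and not res.is_water)]
    if not residues:
        raise AnalysisError("no residues eligible for the network")
    graph = nx.Graph()
    node_of: dict[int, str] = {}
    for ridx, res in residues:
        key = node_key(res.chain_id, res.seq_id, res.insertion_code)
        graph.add_node(key, chain=res.chain_id, seq_id=res.seq_id,
                       name=res.name, residue_index=ridx)
        node_of[ridx] = key

    bonds = topology.bonds if topology.bonds else perceive_bonds(topology, frame)
    resix = topology.atom_residue_index
    bonded_residues = set()
    for i, j in bonds:
        ri, rj = int(resix[i]), int(resix[j])
        if ri != rj:
            bonded_residues.add((min(ri, rj), max(ri, rj)))

    heavy_atoms = []
    owner = []
    eligible = set(node_of)
    for a, atom in enumerate(topology.atoms):
        if atom.is_heavy and atom.residue_index in eligible:
            heavy_atoms.append(a)
            owner.append(atom.residue_index)
    heavy_atoms = np.asarray(heavy_atoms, int)
    owner = np.asarray(owner, int)
    xyz = frame[heavy_atoms]
    tree = cKDTree(xyz)
    min_dist: dict[tuple[int, int], float] = {}
    for ka, kb in tree.query_pairs(cutoff):
        ra, rb = int(owner[ka]), int(owner[kb])
        if ra == rb:
            continue
        pair = (min(ra, rb), max(ra, rb))
        if pair in bonded_residues:
            continue
        d = float(np.linalg.norm(xyz[ka] - xyz[kb]))
        if d >= cutoff:
            continue
        if pair not in min_dist or d < min_dist[pair]:
            min_dist[pair] = d
    for (ra, rb), d in min_dist.items():
        graph.add_edge(node_of[ra], node_of[rb], distance=d)
    return graph


def annotate_strengths(graph: nx.Graph, dccm: DCCMMatrix,
                       topology: Topology) -> nx.Graph:
    """Attach |C_ij| edge strengths and correlation-weighted node degrees.

    The DCCM rows must correspond (via its atom selection) to one atom per
    residue of the graph; a graph residue missing from the DCCM raises an
    error naming it.  Returns the same graph, modified in place.
    """
    row_of_residue = {}
    for row, atom_index in enumerate(np.asarray(dccm.selection, int)):
        row_of_residue[int(topology.atoms[atom_index].residue_index)] = row
    for node, data in graph.nodes(data=True):
        if data["residue_index"] not in row_of_residue:
            raise AnalysisError(f"residue {node} missing from the DCCM selection")
    for u, v, data in graph.edges(data=True):
        i = row_of_residue[graph.nodes[u]["residue_index"]]
        j = row_of_residue[graph.nodes[v]["residue_index"]]
        data["strength"] = float(abs(dccm.matrix[i, j]))
    for node in graph.nodes:
        graph.nodes[node]["weighted_degree"] = float(
            sum(graph.edges[node, nb].get("strength", 0.0)
                for nb in graph.neighbors(node)))
    return graph


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------

@dataclass
class TopologyStats:
    """Whole-network descriptors (the usual network-analyzer panel)."""

    clustering_coefficient: float
    characteristic_path_length: float
    diameter: int
    radius: int
    centralization: float
    density: float
    heterogeneity: float
    avg_neighbors: float
    n_nodes: int
    n_edges: int
    n_components: int

    def to_tsv(self, path) -> None:
        rows = [
            ("Clustering coefficients (C)", f"{self.clustering_coefficient:.3f}"),
            ("Connected component", str(self.n_components)),
            ("Network diameter", str(self.diameter)),
            ("Network radius", str(self.radius)),
            ("Network centralization", f"{self.centralization:.3f}"),
            ("Characteristic path length (L)", f"{self.characteristic_path_length:.3f}"),
            ("Avg.# of neighbors (K)", f"{self.avg_neighbors:.3f}"),
            ("No. of nodes", str(self.n_nodes)),
            ("Network density", f"{self.density:.3f}"),
            ("Network heterogeneity", f"{self.heterogeneity:.3f}"),
            ("No. of edges", str(self.n_edges)),
        ]
        with open(path, "w") as fh:
            for k, v in rows:
                fh.write(f"{k}\t{v}\n")


def topology_stats(graph: nx.Graph) -> TopologyStats:
    """Compute the descriptor panel of :class:`TopologyStats`.

    C is the mean local clustering coefficient (degree < 2 contributes 0);
    L averages shortest-path lengths over connected pairs only; diameter
    and radius are the extreme node eccentricities within components
    (infinite pairs excluded); density = 2E/(N(N-1)); heterogeneity =
    std(degree)/mean(degree); centralization =
    (N/(N-2)) (k_max/(N-1) - density).
    """
    n = graph.number_of_nodes()
    if n < 1:
        raise AnalysisError("empty graph")
    e = graph.number_of_edges()
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    clustering = float(np.mean(list(nx.clustering(graph).values())))
    total_len, total_pairs = 0, 0
    eccentricities = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_nodes() == 1:
            eccentricities.append(0)
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        for u, dists in lengths.items():
            eccentricities.append(max(dists.values()))
            total_len += sum(dists.values())
            total_pairs += len(dists) - 1
    cpl = total_len / total_pairs if total_pairs else 0.0
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_deg = degrees.mean() if n else 0.0
    heterogeneity = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0
    if n > 2:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    else:
        centralization = 0.0
    return TopologyStats(
        clustering_coefficient=clustering,
        characteristic_path_length=float(cpl),
        diameter=int(max(eccentricities)) if eccentricities else 0,
        radius=int(min(eccentricities)) if eccentricities else 0,
        centralization=float(centralization),
        density=float(density),
        heterogeneity=heterogeneity,
        avg_neighbors=float(mean_deg),
        n_nodes=n,
        n_edges=e,
        n_components=nx.number_connected_components(graph),
    )


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------

@dataclass
class CentralityProfile:
    """Per-node betweenness B_k and closeness C_x (both in [0, 1]) plus the
    correlation-weighted degree where strengths are present."""

    betweenness: dict
    closeness: dict
    weighted_degree: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# node\tbetweenness\tcloseness\tweighted_degree\n")
            for node in self.betweenness:
                wd = self.weighted_degree.get(node, float("nan"))
                fh.write(f"{node}\t{self.betweenness[node]:.6f}\t"
                         f"{self.closeness[node]:.6f}\t{wd:.6f}\n")


def centralities(graph: nx.Graph) -> CentralityProfile:
    """Betweenness (shortest-path pair counting, normalised by
    (N-1)(N-2)/2) and within-component closeness
    (reachable count / summed distance to reachable nodes)."""
    if graph.number_of_nodes() < 3:
        raise AnalysisError("centralities need at least 3 nodes")
    bk = nx.betweenness_centrality(graph, normalized=True)
    cx = {}
    for node in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, node)
        total = sum(dists.values())
        reach = len(dists) - 1
        cx[node] = reach / total if total > 0 else 0.0
    wd = {node: data["weighted_degree"] for node, data in graph.nodes(data=True)
          if "weighted_degree" in data}
    return CentralityProfile(betweenness=bk, closeness=cx, weighted_degree=wd)


def degree_distribution(graph: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of node degrees: (degree values, counts)."""
    degrees = np.array([d for _, d in graph.degree()], dtype=int)
    values, counts = np.unique(degrees, return_counts=True)
    return values, counts


# ---------------------------------------------------------------------------
# Communities (Girvan-Newman)
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    """Node -> community label; communities of size <= 2 count as isolated."""

    labels: dict
    n_communities: int
    n_integrated: int
    n_isolated: int
    modularity: float

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return [out[k] for k in sorted(out)]


def _most_valuable_edge(graph: nx.Graph):
    """Max-betweenness edge; ties broken by the lexicographically smallest
    sorted node pair (deterministic removal order)."""
    ebc = nx.edge_betweenness_centrality(graph)
    best = None
    for (u, v), value in ebc.items():
        key = (-value, tuple(sorted((str(u), str(v)))))
        if best is None or key < best[0]:
            best = (key, (u, v))
    return best[1]


def _partition_record(graph, communities):
    comms = [set(c) for c in communities]
    if graph.number_of_edges() > 0:
        mod = nx.community.modularity(graph, comms)
    else:
        mod = 0.0
    return comms, mod


def girvan_newman(graph: nx.Graph, stop: str | int = "max_modularity"
                  ) -> CommunityPartition:
    """Divisive community detection by repeated highest-betweenness edge removal.

    ``stop`` is either ``"max_modularity"`` (return the partition of maximal
    modularity over the removal sequence, including the initial
    component partition) or a target community count k (first partition with
    >= k communities).  Communities of size <= 2 are counted as isolated,
    larger ones as integrated.
    """
    if graph.number_of_nodes() < 1:
        raise AnalysisError("empty graph")
    initial = list(nx.connected_components(graph))
    candidates = [_partition_record(graph, initial)]
    if graph.number_of_edges() > 0:
        for communities in nx.community.girvan_newman(
                graph, most_valuable_edge=_most_valuable_edge):
            candidates.append(_partition_record(graph, communities))
            if isinstance(stop, int) and len(communities) >= stop:
                break

    if isinstance(stop, int):
        chosen, modularity = candidates[-1]
        for comms, mod in candidates:
            if len(comms) >= stop:
                chosen, modularity = comms, mod
                break
    elif stop == "max_modularity":
        chosen, modularity = max(candidates, key=lambda cm: cm[1])
    else:
        raise AnalysisError(f"unknown stop criterion {stop!r}")

    chosen = sorted(chosen, key=lambda c: sorted(str(n) for n in c)[0])
    labels = {}
    for lab, comm in enumerate(chosen):
        for node in comm:
            labels[node] = lab
    sizes = [len(c) for c in chosen]
    n_isolated = sum(1 for s in sizes if s <= 2)
    return CommunityPartition(labels=labels, n_communities=len(chosen),
                              n_integrated=len(chosen) - n_isolated,
                              n_isolated=n_isolated,
                              modularity=float(modularity))


# ---------------------------------------------------------------------------
# Inter-chain communication pathways
# ---------------------------------------------------------------------------

@dataclass
class PathwaySubgraph:
    """Union of all shortest paths from a source residue into a target chain."""

    source: str
    target_chain: str
    nodes: set
    edges: set
    bridging_pairs: set
    terminated: bool

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def interface_pathway(graph: nx.Graph, source: str,
                      target_chain: str) -> PathwaySubgraph:
    """All-shortest-path communication subgraph from ``source`` into
    ``target_chain``.

    Breadth-first search (unweighted hop count) from the source yields the
    shortest-path predecessor DAG; the subgraph is the union of ALL
    shortest paths (ties retained) from the source to every reachable node
    of the target chain.  Bridging pairs are the inter-chain edges of the
    subgraph.  If no target-chain node is reachable the union is taken to
    the furthest reachable frontier instead and the result is flagged
    ``terminated`` (the signal cannot propagate into the target chain).
    """
    if source not in graph:
        raise AnalysisError(f"source node {source!r} not in graph")
    pred, dist = nx.predecessor(graph, source, return_seen=True)
    targets = [n for n in graph.nodes
               if graph.nodes[n].get("chain") == target_chain
               and n in dist and n != source]
    terminated = len(targets) == 0
    if terminated:
        max_d = max(dist.values())
        targets = [n for n, d in dist.items() if d == max_d and n != source]
    nodes: set = {source}
    edges: set = set()
    stack = list(targets)
    visited = set()
    while stack:
        node = stack.pop()
        if node in visited:
            continue
        visited.add(node)
        nodes.add(node)
        for p in pred.get(node, []):
            edges.add(frozenset((node, p)))
            nodes.add(p)
            if p not in visited:
                stack.append(p)
    bridging = set()
    for edge in edges:
        u, v = tuple(edge)
        if graph.nodes[u].get("chain") != graph.nodes[v].get("chain"):
            bridging.add(edge)
    return PathwaySubgraph(source=source, target_chain=target_chain,
                           nodes=nodes, edges=edges, bridging_pairs=bridging,
                           terminated=terminated)


# ---------------------------------------------------------------------------
# All-pairs distances and exports
# ---------------------------------------------------------------------------

def all_pairs_distances(graph: nx.Graph, weighted: bool = False) -> dict:
    """All-pairs shortest-path lengths (Floyd-Warshall; hop count by default,
    or 1/strength edge lengths in the weighted mode)."""
    if weighted:
        for u, v, data in graph.edges(data=True):
            s = data.get("strength", 0.0)
            data["_len"] = 1.0 / s if s > 0 else np.inf
        return nx.floyd_warshall(graph, weight="_len")
    return nx.floyd_warshall(graph, weight=None)


def edges_to_tsv(graph: nx.Graph, path) -> None:
    """Edge-list export: chain:resid pairs with distance and strength."""
    with open(path, "w") as fh:
        fh.write("# node_a\tnode_b\tdistance_nm\tstrength\n")
        for u, v, data in sorted(graph.edges(data=True)):
            s = data.get("strength", float("nan"))
            fh.write(f"{u}\t{v}\t{data.get('distance', float('nan')):.4f}\t{s:.4f}\n")


def to_gml(graph: nx.Graph, path) -> None:
    """Write the network in GML, a standard plain-text graph-exchange format."""
    nx.write_gml(graph, path)
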