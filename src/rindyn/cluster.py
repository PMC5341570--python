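"""Conformational clustering: pairwise RMSD matrix and Jarvis-Patrick.

Jarvis-Patrick joins two frames when each lists the other among its M
nearest neighbours (by pairwise superposed RMSD) and they share at least P
common neighbours; clusters are the connected components of the resulting
join graph.  The procedure is deterministic and non-iterative (ties in the
neighbour lists break toward the lower frame index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .metrics import kabsch_superpose
from .structure import Trajectory

__all__ = ["ClusterAssignment", "rmsd_matrix", "jarvis_patrick", "representative"]


@dataclass
class ClusterAssignment:
    """Per-frame labels (dense from 0; sizes sum to n_frames)."""

    labels: np.ndarray
    sizes: np.ndarray
    m_neighbors: int
    p_shared: int
    rmsd_cutoff: float | None = None

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def rmsd_matrix(traj: Trajectory, selection) -> np.ndarray:
    """Symmetric frame x frame matrix of pairwise superposed RMSD (nm)."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AnalysisError("empty selection")
    if traj.n_frames < 2:
        raise AnalysisError("need at least 2 frames")
    n = traj.n_frames
    coords = traj.coordinates[:, selection, :]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_superpose(coords[i], coords[j]).rmsd
    return mat


def _neighbor_lists(dist: np.ndarray, m: int,
                    rmsd_cutoff: float | None) -> list[set[int]]:
    """M nearest neighbours of each frame (self excluded).

    Frames whose distance ties with the M-th nearest are all included, so
    the relation stays symmetric on degenerate matrices (e.g. all-identical
    frames form one cluster); with distinct distances this is exactly the
    M-nearest list.
    """
    n = dist.shape[0]
    out = []
    for i in range(n):
        order = np.lexsort((np.arange(n), dist[i]))  # distance, then index
        order = order[order != i]
        if rmsd_cutoff is not None:
            order = order[dist[i][order] < rmsd_cutoff]
        if order.size > m:
            threshold = dist[i][order[m - 1]]
            keep = order[dist[i][order] <= threshold]
        else:
            keep = order
        out.append(set(keep.tolist()))
    return out


def jarvis_patrick(dist: np.ndarray, m_neighbors: int = 10, p_shared: int = 3,
                   rmsd_cutoff: float | None = None) -> ClusterAssignment:
    """Jarvis-Patrick clustering of a distance matrix.

    Neighbour lists hold the M nearest frames (self excluded; distances
    tied with the M-th nearest are all kept); frames i and j are joined
    iff each lists the other
    and |neighbors(i) & neighbors(j)| >= P.  Clusters are connected
    components of the join graph, labelled 0.. in order of first member.
    An optional ``rmsd_cutoff`` restricts neighbour lists to frames closer
    than the cutoff (non-default mode).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-9):
        raise AnalysisError("distance matrix must be square and symmetric")
    if m_neighbors >= n:
        raise AnalysisError("m_neighbors must be smaller than the frame count")
    neighbors = _neighbor_lists(dist, m_neighbors, rmsd_cutoff)

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(n):
        for j in neighbors[i]:
            if j <= i:
                continue
            if i in neighbors[j] and len(neighbors[i] & neighbors[j]) >= p_shared:
                union(i, j)

    labels = np.empty(n, dtype=int)
    label_of_root: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        if r not in label_of_root:
            label_of_root[r] = len(label_of_root)
        labels[i] = label_of_root[r]
    sizes = np.bincount(labels)
    return ClusterAssignment(labels=labels, sizes=sizes,
                             m_neighbors=m_neighbors, p_shared=p_shared,
                             rmsd_cutoff=rmsd_cutoff)


def filter_small_clusters(assignment: ClusterAssignment,
                          min_size: int) -> np.ndarray:
    """Relabel clusters below ``min_size`` as -1 (unclustered singletons)."""
    labels = assignment.labels.copy()
    for lab, size in enumerate(assignment.sizes):
        if size < min_size:
            labels[labels == lab] = -1
    return labels


def representative(assignment: ClusterAssignment, dist: np.ndarray,
                   cluster: int) -> int:
    """Medoid frame of a cluster: member minimising the summed distance to
    the other members (ties -> lowest frame index)."""
    members = assignment.members(cluster)
    if members.size == 0:
        raise AnalysisError(f"unknown or empty cluster label {cluster}")
    sub = np.asarray(dist)[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])
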