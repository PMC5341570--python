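"""Essential dynamics: positional covariance PCA, projections, DCCM, overlaps.

The positional covariance matrix of superposed coordinates is
eigendecomposed; eigenvectors are the principal modes of collective motion
and eigenvalues their mean-square fluctuation (nm^2).  Subspace similarity
between two trajectories is quantified by the per-vector inner products,
the root-mean-square inner product (RMSIP) over the first k eigenvectors,
and the normalised Hess covariance overlap.  Inter-residue coupling is
summarised by the dynamic cross-correlation matrix (DCCM).

The covariance is mass-unweighted (C-alpha coordinates), and the
superposition target is the converged iterative mean structure (initial fit
to frame 0, then two refinement passes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .metrics import superpose_trajectory
from .structure import Topology, Trajectory

__all__ = [
    "PCAResult",
    "DCCMMatrix",
    "OverlapReport",
    "build_pca",
    "project",
    "dccm",
    "subspace_overlap",
    "porcupine_export",
]


@dataclass
class PCAResult:
    """Eigenvalues (nm^2, descending), orthonormal 3N eigenvectors (rows),
    variance fractions and the mean structure used for centring."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_components, 3N)
    variance_fractions: np.ndarray
    mean: np.ndarray          # (n_sel, 3)
    selection: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass
class DCCMMatrix:
    """Residue x residue normalised displacement correlations in [-1, 1]."""

    matrix: np.ndarray
    selection: np.ndarray

    def to_text(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.6f", delimiter="\t")


@dataclass
class OverlapReport:
    per_vector: np.ndarray      # |v_a,i . v_b,i| for i < k
    rmsip: float
    covariance_overlap: float
    k: int


def _superposed_deviations(traj: Trajectory, selection: np.ndarray,
                           superpose: bool = True):
    """Centre the selected coordinates on the iterative-mean structure.

    Returns (deviations (frames, 3n), mean (n_sel, 3)).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AnalysisError("empty selection")
    if traj.n_frames < 2:
        raise AnalysisError("need at least 2 frames")
    sub = traj.coordinates[:, selection, :]
    if superpose:
        sub_traj = Trajectory(sub, traj.times, _dummy_topology(selection.size))
        coords = superpose_trajectory(sub_traj, sub[0], np.arange(selection.size))
        for _ in range(2):  # refinement passes onto the running mean
            mean = coords.mean(axis=0)
            sub_traj = Trajectory(coords, traj.times, sub_traj.topology)
            coords = superpose_trajectory(sub_traj, mean, np.arange(selection.size))
        sub = coords
    mean = sub.mean(axis=0)
    dev = (sub - mean[None]).reshape(traj.n_frames, -1)
    return dev, mean


def _dummy_topology(n_atoms: int) -> Topology:
    from .synth import _point_topology
    return _point_topology(n_atoms)


def build_pca(traj: Trajectory, selection, superpose: bool = True) -> PCAResult:
    """Covariance PCA of the selected coordinates.

    Frames are superposed onto the iterative mean (rotation/translation
    eliminated), the 3N x 3N positional covariance is formed, and its
    symmetric eigendecomposition returned in descending eigenvalue order.
    ``variance_fractions`` are eigenvalue / trace.
    """
    selection = np.asarray(selection, dtype=int)
    dev, mean = _superposed_deviations(traj, selection, superpose)
    n_frames = dev.shape[0]
    if n_frames - 1 < dev.shape[1]:
        warnings.warn("fewer frames than coordinates: eigenvalue spectrum truncated "
                      f"at rank <= {n_frames - 1}")
    cov = dev.T @ dev / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T
    evals = np.where(np.abs(evals) < 1e-14, 0.0, evals)
    trace = evals.sum()
    fractions = evals / trace if trace > 0 else np.zeros_like(evals)
    return PCAResult(eigenvalues=evals, eigenvectors=evecs,
                     variance_fractions=fractions, mean=mean, selection=selection)


def project(traj: Trajectory, pca: PCAResult, k: int) -> np.ndarray:
    """Project frames onto the first k principal modes; returns (frames, k)."""
    if k > pca.n_components:
        raise AnalysisError("k exceeds available eigenvectors")
    sel = pca.selection
    sub = traj.coordinates[:, sel, :]
    sub_traj = Trajectory(sub, traj.times, _dummy_topology(sel.size))
    coords = superpose_trajectory(sub_traj, pca.mean, np.arange(sel.size))
    dev = (coords - pca.mean[None]).reshape(traj.n_frames, -1)
    return dev @ pca.eigenvectors[:k].T


def dccm(traj: Trajectory, selection, stride: int = 1,
         superpose: bool = True) -> DCCMMatrix:
    """Dynamic cross-correlation matrix of the selected atoms.

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) with deviations taken
    from the mean after superposition; zero-variance atoms get a zero row
    with unit diagonal (and a warning).
    """
    selection = np.asarray(selection, dtype=int)
    strided = traj.slice_frames(None, None, stride) if stride > 1 else traj
    if strided.n_frames < 2:
        raise AnalysisError("need at least 2 strided frames")
    dev, _ = _superposed_deviations(strided, selection, superpose)
    n_sel = selection.size
    dev3 = dev.reshape(strided.n_frames, n_sel, 3)
    inner = np.einsum("fid,fjd->ij", dev3, dev3) / strided.n_frames
    var = np.diag(inner).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance atom(s) in DCCM")
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    mat = inner / denom
    mat[zero, :] = 0.0
    mat[:, zero] = 0.0
    np.fill_diagonal(mat, 1.0)
    mat = np.clip(mat, -1.0, 1.0)
    return DCCMMatrix(matrix=mat, selection=selection)


def subspace_overlap(a: PCAResult, b: PCAResult, k: int = 10) -> OverlapReport:
    """Similarity of two essential subspaces.

    per_vector: |v_a,i . v_b,i| for the first k pairs.
    RMSIP = sqrt( (1/k) sum_i sum_j (v_a,i . v_b,j)^2 ) over the first k.
    covariance_overlap: normalised Hess formula
    1 - sqrt( (sum(la + lb) - 2 sum_ij sqrt(la_i lb_j)(v_a,i.v_b,j)^2)
              / sum(la + lb) ).
    """
    if a.eigenvectors.shape[1] != b.eigenvectors.shape[1]:
        raise AnalysisError("dimension mismatch between PCA results")
    k = int(min(k, a.n_components, b.n_components))
    va, vb = a.eigenvectors[:k], b.eigenvectors[:k]
    dots = va @ vb.T
    per_vector = np.abs(np.diag(dots))
    rmsip = float(np.sqrt((dots ** 2).sum() / k))

    la = np.clip(a.eigenvalues, 0.0, None)
    lb = np.clip(b.eigenvalues, 0.0, None)
    all_dots = a.eigenvectors @ b.eigenvectors.T
    cross = (np.sqrt(np.outer(la, lb)) * all_dots ** 2).sum()
    denom = la.sum() + lb.sum()
    if denom <= 0:
        cov_overlap = 1.0
    else:
        inner = max(denom - 2.0 * cross, 0.0)
        cov_overlap = float(1.0 - np.sqrt(inner / denom))
    return OverlapReport(per_vector=per_vector, rmsip=rmsip,
                         covariance_overlap=cov_overlap, k=k)


def porcupine_export(pca: PCAResult, component: int, scale: float,
                     topology: Topology | None = None,
                     path=None):
    """Per-atom arrows for one principal mode.

    Each selected atom gets a record (atom_index, start_xyz, end_xyz) with
    start = mean position and end = start + scale * eigenvector segment
    (nm per unit mode amplitude).  Returns the table; optionally writes TSV.
    """
    if component >= pca.n_components:
        raise AnalysisError("component not available")
    vec = pca.eigenvectors[component].reshape(-1, 3)
    start = pca.mean
    end = start + scale * vec
    table = np.column_stack([pca.selection, start, end])
    if path is not None:
        with open(path, "w") as fh:
            fh.write("# atom\tstart_x\tstart_y\tstart_z\tend_x\tend_y\tend_z\n")
            for row in table:
                fh.write(f"{int(row[0])}\t" + "\t".join(f"{v:.6f}" for v in row[1:])
                         + "\n")
    return table
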