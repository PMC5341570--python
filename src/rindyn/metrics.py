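"""Geometric time-series analyses of trajectories.

Superposition (Kabsch), RMSD, radius of gyration, RMSF, centre-of-mass
distances, contact counts, dihedral series, hydration-shell counts and
paired-profile comparison (Pearson r / least-squares line / residual
variance).  All lengths in nm, times in ps, angles in degrees.

Periodic boundary conditions are NOT applied anywhere in this module:
input trajectories are assumed to be whole and clustered (as produced by
standard trajectory post-processing); distances are plain Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import dihedral_deg
from .errors import AnalysisError, SuperpositionError
from .structure import Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "TimeSeries",
    "ProfileComparison",
    "kabsch_superpose",
    "superpose_trajectory",
    "rmsd_series",
    "radius_of_gyration",
    "rmsf",
    "compare_profiles",
    "com_distance",
    "contact_count",
    "dihedral_series",
    "chi_atom_indices",
    "hydration_count",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: ``rotation @ mobile + translation ~ reference``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass
class TimeSeries:
    """A per-frame scalar series with times in ps."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    unit: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape[0] != self.values.shape[0]:
            raise AnalysisError("times and values must have equal length")

    def to_tsv(self, path) -> None:
        """Write as 2-column TSV (time_ps, value)."""
        with open(path, "w") as fh:
            fh.write(f"# time_ps\t{self.label or 'value'}"
                     f"{('_' + self.unit) if self.unit else ''}\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6g}\t{v:.8g}\n")


@dataclass
class ProfileComparison:
    """OLS comparison of two profiles: b regressed on a.

    ``residual_variance_s2`` is the residual sum of squares divided by
    (n - 2), i.e. the variance of the data around the fitted line.
    """

    pearson_r: float
    slope: float
    intercept: float
    residual_variance_s2: float


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1, reflections excluded) and
    translation minimising the weighted squared deviation, plus the
    resulting RMSD.  Requires >= 3 non-collinear atoms.
    """
    from scipy.spatial.transform import Rotation

    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise SuperpositionError("coordinate arrays must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise SuperpositionError("superposition requires at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise SuperpositionError("invalid weights")
    wfrac = w / w.sum()
    ref_c = ref - wfrac @ ref
    mob_c = mob - wfrac @ mob
    # collinearity check on the reference
    if np.linalg.matrix_rank(ref_c * np.sqrt(wfrac)[:, None], tol=1e-10) < 2:
        raise SuperpositionError("degenerate (collinear) geometry")
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    rmat = rot.as_matrix()
    translation = (wfrac @ ref) - rmat @ (wfrac @ mob)
    moved = mob_c @ rmat.T
    rmsd = float(np.sqrt(np.sum(wfrac[:, None] * (moved - ref_c) ** 2)))
    return SuperpositionResult(rotation=rmat, translation=translation, rmsd=rmsd)


def _apply(sup: SuperpositionResult, coords: np.ndarray) -> np.ndarray:
    return coords @ sup.rotation.T + sup.translation


def superpose_trajectory(traj: Trajectory, reference: np.ndarray,
                         fit_selection: np.ndarray,
                         weights: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto ``reference`` over ``fit_selection``;
    returns the transformed full-coordinate array (frames, atoms, 3)."""
    out = np.empty_like(traj.coordinates)
    ref_sel = reference[fit_selection]
    for f in range(traj.n_frames):
        sup = kabsch_superpose(ref_sel, traj.coordinates[f][fit_selection], weights)
        out[f] = _apply(sup, traj.coordinates[f])
    return out


# ---------------------------------------------------------------------------
# RMSD / Rg / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: np.ndarray) -> TimeSeries:
    """Per-frame RMSD (nm) after superposing each frame onto the reference
    over the selection."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AnalysisError("empty selection")
    ref_sel = reference[selection]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sup = kabsch_superpose(ref_sel, traj.coordinates[f][selection])
        values[f] = sup.rmsd
    return TimeSeries(traj.times, values, label="rmsd", unit="nm")


def radius_of_gyration(traj: Trajectory, selection: np.ndarray,
                       mass_weighted: bool = True) -> TimeSeries:
    """Rg(t) = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ), in nm."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AnalysisError("empty selection")
    m = traj.topology.masses[selection] if mass_weighted else np.ones(selection.size)
    mfrac = m / m.sum()
    xyz = traj.coordinates[:, selection, :]
    com = np.einsum("i,fij->fj", mfrac, xyz)
    dev = xyz - com[:, None, :]
    rg = np.sqrt(np.einsum("i,fij->f", mfrac, dev ** 2))
    return TimeSeries(traj.times, rg, label="rg", unit="nm")


def rmsf(traj: Trajectory, selection: np.ndarray,
         fit_selection: np.ndarray | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (nm) about the average structure.

    Frames are first superposed (over ``fit_selection``, default =
    ``selection``) onto frame 0, an average structure is computed, and one
    refinement pass re-superposes onto that average before the fluctuations
    are measured — the standard iterated-mean reference.
    """
    if traj.n_frames < 2:
        raise AnalysisError("rmsf requires at least 2 frames")
    selection = np.asarray(selection, dtype=int)
    fit_sel = selection if fit_selection is None else np.asarray(fit_selection, int)
    coords = superpose_trajectory(traj, traj.coordinates[0], fit_sel)
    mean = coords.mean(axis=0)
    traj2 = Trajectory(coords, traj.times, traj.topology)
    coords = superpose_trajectory(traj2, mean, fit_sel)
    mean = coords.mean(axis=0)
    dev = coords[:, selection, :] - mean[None, selection, :]
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------

def compare_profiles(a, b) -> ProfileComparison:
    """Pearson r and OLS line of b on a, with residual variance s^2 = RSS/(n-2)."""
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise AnalysisError("profiles must be equal-length 1-D arrays of size >= 3")
    if np.ptp(a) == 0:
        raise AnalysisError("undefined correlation: zero variance in first profile")
    res = stats.linregress(a, b)
    resid = b - (res.slope * a + res.intercept)
    s2 = float((resid ** 2).sum() / (a.size - 2))
    return ProfileComparison(pearson_r=float(res.rvalue), slope=float(res.slope),
                             intercept=float(res.intercept),
                             residual_variance_s2=s2)


# ---------------------------------------------------------------------------
# Distances / contacts / dihedrals / hydration
# ---------------------------------------------------------------------------

def com_distance(traj: Trajectory, selection_a, selection_b) -> TimeSeries:
    """Distance (nm) between the mass-weighted centres of two selections."""
    sa = np.asarray(selection_a, dtype=int)
    sb = np.asarray(selection_b, dtype=int)
    if sa.size == 0 or sb.size == 0:
        raise AnalysisError("empty selection")
    masses = traj.topology.masses
    coms = []
    for sel in (sa, sb):
        m = masses[sel] / masses[sel].sum()
        coms.append(np.einsum("i,fij->fj", m, traj.coordinates[:, sel, :]))
    dist = np.linalg.norm(coms[0] - coms[1], axis=1)
    return TimeSeries(traj.times, dist, label="com_distance", unit="nm")


def contact_count(traj: Trajectory, selection_a, selection_b,
                  cutoff: float) -> TimeSeries:
    """Number of atom pairs (i in A, j in B, i != j) strictly closer than
    ``cutoff`` nm, per frame; each unordered pair is counted once."""
    from scipy.spatial import cKDTree

    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    sa = np.asarray(selection_a, dtype=int)
    sb = np.asarray(selection_b, dtype=int)
    counts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.coordinates[f]
        if sa.size == 0 or sb.size == 0:
            continue
        tree_b = cKDTree(xyz[sb])
        pairs = cKDTree(xyz[sa]).query_ball_tree(tree_b, cutoff)
        seen = set()
        for ia, neighbors in zip(sa, pairs):
            for jb in neighbors:
                j = sb[jb]
                if ia == j:
                    continue
                d = np.linalg.norm(xyz[ia] - xyz[j])
                if d < cutoff:  # strict inequality; boundary excluded
                    seen.add((min(ia, j), max(ia, j)))
        counts[f] = len(seen)
    return TimeSeries(traj.times, counts, label="contacts", unit="count")


_CHI_ATOMS = {
    "chi1": ("N", "CA", "CB", "CG"),
    "chi2": ("CA", "CB", "CG", "CD1"),
}


def chi_atom_indices(topology: Topology, chain_id: str, seq_id: int,
                     which: str = "chi1") -> np.ndarray:
    """Resolve the four atom indices of chi1 (N-CA-CB-CG) or chi2
    (CA-CB-CG-CD1) for a named residue."""
    if which not in _CHI_ATOMS:
        raise AnalysisError(f"unknown dihedral {which!r}")
    res = next((r for r in topology.residues
                if r.chain_id == chain_id and r.seq_id == seq_id), None)
    if res is None:
        raise AnalysisError(f"residue {chain_id}:{seq_id} not found")
    names = {topology.atoms[i].name: i for i in res.atom_indices}
    try:
        return np.array([names[a] for a in _CHI_ATOMS[which]])
    except KeyError as exc:
        raise AnalysisError(f"residue {res.label()} lacks atom {exc}") from None


def dihedral_series(traj: Trajectory, atoms) -> TimeSeries:
    """Signed dihedral (degrees, range (-180, 180]) over the four given atoms."""
    atoms = np.asarray(atoms, dtype=int)
    if atoms.size != 4 or len(set(atoms.tolist())) != 4:
        raise AnalysisError("dihedral requires 4 distinct atom indices")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        p = traj.coordinates[f][atoms]
        values[f] = dihedral_deg(p[0], p[1], p[2], p[3])
    return TimeSeries(traj.times, values, label="dihedral", unit="deg")


def hydration_count(traj: Trajectory, solute, water_residues=None,
                    cutoff: float = 0.4) -> TimeSeries:
    """Number of water residues with >= 1 atom within ``cutoff`` nm of >= 1
    solute atom (first hydration shell; each water counted once per frame)."""
    from scipy.spatial import cKDTree

    top = traj.topology
    solute = np.asarray(solute, dtype=int)
    if water_residues is None:
        water_residues = [i for i, r in enumerate(top.residues) if r.is_water]
    water_atoms = []
    water_owner = []
    for ri in water_residues:
        for ai in top.residues[ri].atom_indices:
            water_atoms.append(ai)
            water_owner.append(ri)
    water_atoms = np.asarray(water_atoms, dtype=int)
    water_owner = np.asarray(water_owner, dtype=int)
    counts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        if water_atoms.size == 0 or solute.size == 0:
            continue
        xyz = traj.coordinates[f]
        tree = cKDTree(xyz[solute])
        d, _ = tree.query(xyz[water_atoms], k=1)
        counts[f] = len(set(water_owner[d < cutoff].tolist()))
    return TimeSeries(traj.times, counts, label="hydration", unit="count")
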