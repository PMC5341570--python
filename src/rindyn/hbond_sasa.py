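"""Geometric hydrogen-bond detection and Shrake-Rupley solvent accessibility.

Hydrogen bonds follow the classical geometric criterion used by trajectory
analysis suites: OH and NH groups donate, N and O accept, and a bond is
counted when the donor-acceptor distance is within 0.35 nm and the
hydrogen-donor-acceptor angle (vertex at the donor heavy atom) is within
30 degrees.  Deposited crystal structures usually lack hydrogens, so amide
hydrogens are constructed geometrically; hydroxyl hydrogens cannot be placed
uniquely without a rotamer choice, and such donors are skipped (counted in
the diagnostics record).

SASA uses the Shrake-Rupley sphere-point method with a deterministic
golden-spiral point set and a Bondi-style per-element radius table
(:mod:`rindyn.constants`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import angle_deg
from .constants import AMIDE_NH_LENGTH_NM, vdw_radius_of
from .errors import AnalysisError
from .metrics import TimeSeries
from .structure import Topology, Trajectory
from .synth import amide_hydrogen

__all__ = [
    "HBondCriteria",
    "HBond",
    "SasaResult",
    "find_hbonds",
    "hbond_series",
    "sasa",
    "default_donors_acceptors",
]


@dataclass
class HBondCriteria:
    """Cutoffs: donor-acceptor distance (nm) and H-donor-acceptor angle (deg)."""

    max_donor_acceptor_distance: float = 0.35
    max_hda_angle: float = 30.0

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0:
            raise AnalysisError("distance cutoff must be positive")
        if not 0 < self.max_hda_angle <= 180:
            raise AnalysisError("angle cutoff must be in (0, 180]")


@dataclass
class HBond:
    donor: int
    hydrogen: int  # -1 when the hydrogen was constructed geometrically
    acceptor: int
    distance: float
    angle: float


@dataclass
class SasaResult:
    per_atom: np.ndarray  # nm^2, full-topology length (0 outside selection)
    total: float
    probe_radius: float
    n_points: int


# ---------------------------------------------------------------------------
# Donor / acceptor bookkeeping
# ---------------------------------------------------------------------------

def default_donors_acceptors(topology: Topology,
                             exclude_water: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Default donor and acceptor atom sets: N/O heavy atoms (donors must be
    able to carry a hydrogen — proline backbone N excluded)."""
    donors, acceptors = [], []
    for i, atom in enumerate(topology.atoms):
        el = atom.element.upper()
        if el not in ("N", "O") or not atom.is_heavy:
            continue
        res = topology.residues[atom.residue_index]
        if exclude_water and res.is_water:
            continue
        acceptors.append(i)
        if res.name == "PRO" and atom.name == "N":
            continue
        donors.append(i)
    return np.array(donors, dtype=int), np.array(acceptors, dtype=int)


def _donor_hydrogens(topology: Topology, frame: np.ndarray, donors,
                     diagnostics: dict | None):
    """Map donor atom index -> list of (hydrogen_index, hydrogen_xyz).

    Existing bonded hydrogens are used; a missing backbone amide hydrogen is
    built at 0.101 nm from N opposite the bisector of N->CA and N->C(prev).
    Donors whose hydrogen can neither be found nor built are skipped.
    """
    neighbors = topology.bonded_neighbors() if topology.bonds else None
    out: dict[int, list] = {}
    skipped = []
    res_first_atom = {}
    for ridx, res in enumerate(topology.residues):
        names = {topology.atoms[i].name: i for i in res.atom_indices}
        res_first_atom[ridx] = names
    for d in donors:
        hs = []
        if neighbors is not None:
            for j in neighbors[d]:
                if not topology.atoms[j].is_heavy:
                    hs.append((j, frame[j]))
        if not hs and topology.atoms[d].name == "N":
            atom = topology.atoms[d]
            names = res_first_atom[atom.residue_index]
            # naming convention: H/HN is the amide hydrogen on backbone N
            for hname in ("H", "HN"):
                if hname in names and not topology.atoms[names[hname]].is_heavy:
                    hs.append((names[hname], frame[names[hname]]))
                    break
        if not hs and topology.atoms[d].name == "N":
            built = _build_amide_h(topology, frame, d)
            if built is not None:
                hs.append((-1, built))
        if hs:
            out[int(d)] = hs
        else:
            skipped.append(int(d))
    if skipped:
        warnings.warn(f"{len(skipped)} donor(s) without a resolvable hydrogen skipped")
    if diagnostics is not None:
        diagnostics["skipped_donors"] = skipped
    return out


def _build_amide_h(topology: Topology, frame: np.ndarray, n_index: int):
    atom = topology.atoms[n_index]
    ridx = atom.residue_index
    res = topology.residues[ridx]
    if res.name == "PRO":
        return None
    names = {topology.atoms[i].name: i for i in res.atom_indices}
    if "CA" not in names or ridx == 0:
        return None
    prev = topology.residues[ridx - 1]
    if prev.chain_id != res.chain_id:
        return None
    prev_names = {topology.atoms[i].name: i for i in prev.atom_indices}
    if "C" not in prev_names:
        return None
    c_prev = frame[prev_names["C"]]
    if np.linalg.norm(c_prev - frame[n_index]) > 0.25:  # chain break
        return None
    return amide_hydrogen(frame[n_index], frame[names["CA"]], c_prev)


# ---------------------------------------------------------------------------
# Hydrogen-bond detection
# ---------------------------------------------------------------------------

def find_hbonds(frame: np.ndarray, topology: Topology,
                criteria: HBondCriteria | None = None,
                donors: np.ndarray | None = None,
                acceptors: np.ndarray | None = None,
                diagnostics: dict | None = None) -> list[HBond]:
    """Detect hydrogen bonds in one frame.

    A bond is reported iff the donor-acceptor distance is <= the distance
    cutoff, the hydrogen-donor-acceptor angle is <= the angle cutoff,
    donor != acceptor, and the two heavy atoms are not covalently bonded.
    The best (smallest-angle) hydrogen of a donor is reported.
    """
    from scipy.spatial import cKDTree

    frame = np.asarray(frame, dtype=float)
    criteria = criteria or HBondCriteria()
    if donors is None or acceptors is None:
        auto_d, auto_a = default_donors_acceptors(topology)
        donors = auto_d if donors is None else np.asarray(donors, int)
        acceptors = auto_a if acceptors is None else np.asarray(acceptors, int)
    donors = np.asarray(donors, int)
    acceptors = np.asarray(acceptors, int)
    if donors.size == 0 or acceptors.size == 0:
        return []
    bonded = set()
    for i, j in topology.bonds:
        bonded.add((i, j))
        bonded.add((j, i))
    hydrogens = _donor_hydrogens(topology, frame, donors, diagnostics)
    tree = cKDTree(frame[acceptors])
    bonds: list[HBond] = []
    for d, hs in hydrogens.items():
        near = tree.query_ball_point(frame[d], criteria.max_donor_acceptor_distance)
        for ka in near:
            a = int(acceptors[ka])
            if a == d or (d, a) in bonded:
                continue
            dist = float(np.linalg.norm(frame[a] - frame[d]))
            if dist > criteria.max_donor_acceptor_distance:
                continue
            best = None
            for hidx, hxyz in hs:
                ang = angle_deg(hxyz, frame[d], frame[a])
                if best is None or ang < best[1]:
                    best = (hidx, ang)
            if best is not None and best[1] <= criteria.max_hda_angle:
                bonds.append(HBond(donor=int(d), hydrogen=int(best[0]),
                                   acceptor=a, distance=dist, angle=best[1]))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def hbond_series(traj: Trajectory, topology: Topology | None = None,
                 criteria: HBondCriteria | None = None,
                 group_a=None, group_b=None) -> TimeSeries:
    """Per-frame hydrogen-bond count.

    ``group_a``/``group_b`` are residue-index sets.  With ``group_b`` None
    or identical to ``group_a`` the count is intra-group (both partners in
    the group); otherwise inter-group bonds are counted in both directions
    (donor in A / acceptor in B and vice versa).
    """
    top = topology or traj.topology
    n_res = top.n_residues
    group_a = set(range(n_res)) if group_a is None else set(map(int, group_a))
    inter = group_b is not None and set(map(int, group_b)) != group_a
    group_b = group_a if group_b is None else set(map(int, group_b))
    if inter and (group_a & group_b):
        raise AnalysisError("inter-group hydrogen-bond counting needs disjoint groups")
    donors, acceptors = default_donors_acceptors(top)
    resix = top.atom_residue_index
    counts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        bonds = find_hbonds(traj.coordinates[f], top, criteria, donors, acceptors)
        c = 0
        for b in bonds:
            rd, ra = int(resix[b.donor]), int(resix[b.acceptor])
            if inter:
                if (rd in group_a and ra in group_b) or (rd in group_b and ra in group_a):
                    c += 1
            else:
                if rd in group_a and ra in group_a:
                    c += 1
        counts[f] = c
    return TimeSeries(traj.times, counts, label="hbonds", unit="count")


def hbonds_to_tsv(bonds: list[HBond], topology: Topology, path) -> None:
    """Export a bond list as TSV (donor, hydrogen, acceptor, distance, angle)."""
    with open(path, "w") as fh:
        fh.write("# donor\thydrogen\tacceptor\tdistance_nm\tangle_deg\n")
        for b in bonds:
            dl = topology.residue_of(b.donor).label() + "/" + topology.atoms[b.donor].name
            al = topology.residue_of(b.acceptor).label() + "/" + topology.atoms[b.acceptor].name
            hl = "built" if b.hydrogen < 0 else topology.atoms[b.hydrogen].name
            fh.write(f"{dl}\t{hl}\t{al}\t{b.distance:.4f}\t{b.angle:.2f}\n")


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(frame: np.ndarray, topology: Topology, probe_radius: float = 0.14,
         n_points: int = 960, selection: np.ndarray | None = None) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    Per-atom area = (exposed points / n_points) * 4 pi (r_i + probe)^2 using
    the golden-spiral test-point set.  Only atoms in ``selection`` occlude
    and are scored (default: all atoms).
    """
    from scipy.spatial import cKDTree

    frame = np.asarray(frame, dtype=float)
    sel = np.arange(topology.n_atoms) if selection is None else np.asarray(selection, int)
    if sel.size == 0:
        raise AnalysisError("empty selection")
    radii = np.array([vdw_radius_of(topology.atoms[i].element) for i in sel])
    expanded = radii + probe_radius
    xyz = frame[sel]
    sphere = _golden_spiral(n_points)
    max_r = expanded.max()
    tree = cKDTree(xyz)
    per_atom_sel = np.zeros(sel.size)
    for k in range(sel.size):
        pts = xyz[k] + expanded[k] * sphere
        neighbor_idx = [j for j in tree.query_ball_point(xyz[k], expanded[k] + max_r)
                        if j != k]
        if neighbor_idx:
            nb_xyz = xyz[neighbor_idx]
            nb_r = expanded[neighbor_idx]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r ** 2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        per_atom_sel[k] = exposed / n_points * 4.0 * np.pi * expanded[k] ** 2
    per_atom = np.zeros(topology.n_atoms)
    per_atom[sel] = per_atom_sel
    return SasaResult(per_atom=per_atom, total=float(per_atom_sel.sum()),
                      probe_radius=probe_radius, n_points=n_points)


def sasa_series(traj: Trajectory, selection=None, probe_radius: float = 0.14,
                n_points: int = 960) -> TimeSeries:
    """Total SASA per frame (nm^2)."""
    values = np.array([
        sasa(traj.coordinates[f], traj.topology, probe_radius, n_points, selection).total
        for f in range(traj.n_frames)
    ])
    return TimeSeries(traj.times, values, label="sasa", unit="nm2")
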