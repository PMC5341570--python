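"""Synthetic structures and trajectories with known ground truth.

Every analysis stage in this package is validated against data whose answer
is known by construction: correlated Gaussian fluctuations with planted
principal modes, rigid-body isotropic rotational diffusion with a prescribed
diffusion constant, ideal helix/strand backbones built from textbook
dihedrals, multi-state conformational ensembles, minimal donor-acceptor
hydrogen-bond geometries and toy multi-chain bead complexes with a designed
contact topology.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_atom
from .errors import SpecError
from .structure import Atom, Residue, Topology, Trajectory

__all__ = [
    "GaussianTrajSpec",
    "RotDiffSpec",
    "ToyComplexSpec",
    "gen_gaussian_traj",
    "gen_rotational_diffusion",
    "gen_ideal_secondary",
    "gen_toy_complex",
    "gen_multistate_traj",
    "gen_hbond_fixture",
]


# ---------------------------------------------------------------------------
# Topology assembly helper
# ---------------------------------------------------------------------------

def _build_topology(residue_records):
    """Build (Topology, coords) from [(chain, seq_id, res_name, atoms)] where
    atoms is [(atom_name, element, xyz_nm)]."""
    atoms: list[Atom] = []
    residues: list[Residue] = []
    coords = []
    for chain, seq, rname, atom_list in residue_records:
        res = Residue(name=rname, seq_id=seq, chain_id=chain)
        residues.append(res)
        ridx = len(residues) - 1
        for aname, element, xyz in atom_list:
            res.atom_indices.append(len(atoms))
            atoms.append(Atom(name=aname, element=element, residue_index=ridx,
                              is_heavy=element.upper() not in ("H", "D")))
            coords.append(xyz)
    return Topology(atoms, residues), np.asarray(coords, dtype=float)


# ---------------------------------------------------------------------------
# Correlated Gaussian ensembles
# ---------------------------------------------------------------------------

@dataclass
class GaussianTrajSpec:
    """Multivariate-normal ensemble about a reference structure.

    Either ``covariance`` (3N x 3N, nm^2) or a planted-mode description
    (``modes``: k orthonormal 3N-vectors, ``mode_variances``: nm^2 per mode,
    plus isotropic ``noise_variance``) defines the target covariance.
    """

    reference: np.ndarray
    covariance: np.ndarray | None = None
    modes: np.ndarray | None = None
    mode_variances: np.ndarray | None = None
    noise_variance: float = 0.0
    n_frames: int = 1000
    dt_ps: float = 250.0
    seed: int = 0


def gen_gaussian_traj(spec: GaussianTrajSpec) -> Trajectory:
    """Draw i.i.d. frames from N(reference, covariance).

    With a planted-mode spec the covariance is
    ``sum_k var_k m_k m_k^T + noise * I`` so the leading PCA eigenvectors of
    a long trajectory recover the planted modes.  The sample covariance
    converges to the target as ``n_frames`` grows.
    """
    ref = np.asarray(spec.reference, dtype=float)
    n3 = ref.size
    rng = np.random.default_rng(spec.seed)
    if spec.covariance is not None:
        cov = np.asarray(spec.covariance, dtype=float)
        if cov.shape != (n3, n3):
            raise SpecError(f"covariance must be {n3}x{n3}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise SpecError("covariance must be symmetric")
        evals, evecs = np.linalg.eigh(cov)
        if evals.min() < -1e-10 * max(1.0, evals.max()):
            raise SpecError("covariance must be positive semidefinite")
        evals = np.clip(evals, 0.0, None)
        z = rng.standard_normal((spec.n_frames, n3))
        dev = (z * np.sqrt(evals)) @ evecs.T
    else:
        if spec.modes is None:
            dev = np.zeros((spec.n_frames, n3))
            if spec.noise_variance < 0:
                raise SpecError("noise_variance must be >= 0")
        else:
            modes = np.atleast_2d(np.asarray(spec.modes, dtype=float))
            variances = np.atleast_1d(np.asarray(spec.mode_variances, dtype=float))
            if np.any(variances < 0) or spec.noise_variance < 0:
                raise SpecError("variances must be >= 0")
            gram = modes @ modes.T
            if not np.allclose(gram, np.eye(len(modes)), atol=1e-8):
                raise SpecError("planted modes must be orthonormal")
            amp = rng.standard_normal((spec.n_frames, len(modes))) * np.sqrt(variances)
            dev = amp @ modes
        if spec.noise_variance > 0:
            dev = dev + rng.standard_normal((spec.n_frames, n3)) * np.sqrt(
                spec.noise_variance)
    coords = ref.reshape(1, -1, 3) + dev.reshape(spec.n_frames, -1, 3)
    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ps
    return Trajectory(coords, times, _point_topology(ref.reshape(-1, 3).shape[0]))


def _point_topology(n_atoms: int) -> Topology:
    """One-bead-per-residue topology (pseudo-atom CA) for point ensembles."""
    records = [("A", i + 1, "GLY", [("CA", "C", (0, 0, 0))]) for i in range(n_atoms)]
    top, _ = _build_topology(records)
    return top


# ---------------------------------------------------------------------------
# Rigid-body rotational diffusion
# ---------------------------------------------------------------------------

@dataclass
class RotDiffSpec:
    """Isotropic rotational diffusion of a rigid template.

    ``diffusion_constant`` D is in ps^-1; each step applies a random rotation
    whose rotation-vector components are N(0, 2 D dt) so that the P2
    autocorrelation of any body-fixed unit vector decays as exp(-6 D t).
    """

    template: np.ndarray
    diffusion_constant: float
    n_frames: int = 10000
    dt_ps: float = 1.0
    seed: int = 0


def gen_rotational_diffusion(spec: RotDiffSpec) -> Trajectory:
    """Simulate rigid-body isotropic rotational diffusion (see RotDiffSpec)."""
    from scipy.spatial.transform import Rotation

    if spec.diffusion_constant < 0:
        raise SpecError("diffusion constant must be >= 0")
    d, dt = spec.diffusion_constant, spec.dt_ps
    if 6.0 * d * dt > 0.1:
        warnings.warn("timestep too coarse for small-angle rotation sampling "
                      f"(6*D*dt = {6 * d * dt:.3g} > 0.1)")
    template = np.asarray(spec.template, dtype=float)
    center = template.mean(axis=0)
    body = template - center
    rng = np.random.default_rng(spec.seed)
    coords = np.empty((spec.n_frames, template.shape[0], 3))
    coords[0] = template
    if d == 0.0:
        coords[:] = template
    else:
        sigma = np.sqrt(2.0 * d * dt)
        rotvecs = rng.standard_normal((spec.n_frames - 1, 3)) * sigma
        r_total = np.eye(3)
        for f in range(1, spec.n_frames):
            step = Rotation.from_rotvec(rotvecs[f - 1]).as_matrix()
            r_total = step @ r_total
            coords[f] = body @ r_total.T + center
    times = np.arange(spec.n_frames, dtype=float) * dt
    return Trajectory(coords, times, _point_topology(template.shape[0]))


# ---------------------------------------------------------------------------
# Ideal secondary-structure backbones
# ---------------------------------------------------------------------------

# standard backbone internal coordinates (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 0.1458, 0.1525, 0.1329
_B_C_O, _B_N_H = 0.1231, 0.101
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8
_OMEGA = 180.0

_DIHEDRALS = {
    "alpha_helix": (-57.0, -47.0),
    "antiparallel_sheet": (-139.0, 135.0),
    "extended_coil": (-139.0, 135.0),
}


def _build_strand(n_residues: int, phi: float, psi: float) -> list[dict]:
    """Backbone atoms (N, CA, C, O, H) for one chain from ideal dihedrals."""
    res_atoms: list[dict] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])
    c = place_atom(dummy, n, ca, _B_CA_C, _A_N_CA_C, 52.0)
    res_atoms.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, n_residues):
        prev = res_atoms[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_next = place_atom(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = place_atom(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        res_atoms.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl O: in the peptide plane, trans to the next N (psi + 180)
    for i, res in enumerate(res_atoms):
        res["O"] = place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O,
                              psi + 180.0)
    # amide H: opposite the bisector of N-CA and N-C(prev)
    for i in range(1, n_residues):
        res, prev = res_atoms[i], res_atoms[i - 1]
        res["H"] = amide_hydrogen(res["N"], res["CA"], prev["C"])
    return res_atoms


def amide_hydrogen(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Standard amide-H construction: 0.101 nm from N, opposite the bisector
    of the N->CA and N->C(prev) directions (in the peptide plane)."""
    u = (ca - n) / np.linalg.norm(ca - n)
    v = (c_prev - n) / np.linalg.norm(c_prev - n)
    bisector = u + v
    norm = np.linalg.norm(bisector)
    if norm < 1e-8:  # pathological straight angle
        w = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(u, np.array([0.0, 1.0, 0.0]))
        direction = w / np.linalg.norm(w)
    else:
        direction = -bisector / norm
    return n + _B_N_H * direction


def _strand_records(res_atoms, chain, start_seq):
    records = []
    for i, res in enumerate(res_atoms):
        atoms = [("N", "N", res["N"]), ("CA", "C", res["CA"]),
                 ("C", "C", res["C"]), ("O", "O", res["O"])]
        if "H" in res:
            atoms.append(("H", "H", res["H"]))
        records.append((chain, start_seq + i, "GLY", atoms))
    return records


def gen_ideal_secondary(kind: str, n_residues: int) -> tuple[Topology, Trajectory]:
    """Build an ideal alpha helix, two-strand antiparallel sheet or extended coil.

    ``n_residues`` is per-chain for the sheet variant (two chains A and B are
    returned, rigidly placed so that the canonical antiparallel hydrogen
    bonds form).  Helix requires >= 6 residues, sheet strands >= 4.
    """
    if kind not in _DIHEDRALS:
        raise SpecError(f"unknown secondary-structure kind {kind!r}")
    if kind == "alpha_helix" and n_residues < 6:
        raise SpecError("alpha_helix requires n_residues >= 6")
    if kind == "antiparallel_sheet" and n_residues < 4:
        raise SpecError("antiparallel_sheet requires >= 4 residues per strand")
    if n_residues < 1:
        raise SpecError("n_residues must be positive")
    phi, psi = _DIHEDRALS[kind]
    strand = _build_strand(n_residues, phi, psi)
    records = _strand_records(strand, "A", 1)
    if kind == "antiparallel_sheet":
        partner = _place_antiparallel_partner(strand, n_residues)
        records += _strand_records(partner, "B", 1)
    top, coords = _build_topology(records)
    traj = Trajectory(coords[None, :, :], np.array([0.0]), top)
    return top, traj


def _place_antiparallel_partner(strand, n_res):
    """Rigidly place a reversed copy of ``strand`` so the antiparallel
    hydrogen-bond registry (residue i of A pairs with residue n+1-i of B)
    is satisfied: a least-squares fit of the 6-dof placement drives the
    paired N...O distances to 0.29 nm along the N-H directions."""
    from scipy.optimize import least_squares
    from scipy.spatial.transform import Rotation

    partner = [{k: v.copy() for k, v in res.items()} for res in strand]
    names = [k for k in ("N", "CA", "C", "O", "H")]

    def apply(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        trans = params[3:]
        out = []
        for res in partner:
            out.append({k: res[k] @ rot.T + trans for k in res})
        return out

    # wide rung pairs (i, j = n-1-i), both H-bond directions, every other i
    rungs = [(i, n_res - 1 - i) for i in range(0, n_res, 2) if n_res - 1 - i >= 0]

    def residuals(params):
        placed = apply(params)
        res = []
        for i, j in rungs:
            a, b = strand[i], placed[j]
            if "H" in a:
                res.append(np.linalg.norm(a["H"] - b["O"]) - 0.19)
            res.append(np.linalg.norm(a["N"] - b["O"]) - 0.29)
            if "H" in b:
                res.append(np.linalg.norm(b["H"] - a["O"]) - 0.19)
            res.append(np.linalg.norm(b["N"] - a["O"]) - 0.29)
        return np.array(res)

    # start: rotate 180 deg about the strand axis direction midpoint, offset sideways
    axis = strand[-1]["CA"] - strand[0]["CA"]
    axis = axis / np.linalg.norm(axis)
    start_rot = Rotation.from_rotvec(np.pi * axis).as_rotvec()
    center = np.mean([r["CA"] for r in strand], axis=0)
    side = np.cross(axis, strand[0]["C"] - strand[0]["N"])
    side = side / np.linalg.norm(side)
    best = None
    for sign in (1.0, -1.0):
        x0 = np.concatenate([start_rot, center - center @ Rotation.from_rotvec(
            start_rot).as_matrix().T + sign * 0.48 * side])
        sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    return apply(best.x)


# ---------------------------------------------------------------------------
# Toy bead complexes with designed contact topology
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Multi-chain single-bead-residue complex with a designed contact set.

    ``layout="line"`` lays each chain out as a straight bead string
    (consecutive beads in contact); ``layout="cluster"`` packs each chain
    into a compact all-in-contact cluster.  ``bridges`` lists the residue
    pairs ((chain_index, seq_id), (chain_index, seq_id)) that are the only
    inter-chain contacts.  Beads use pseudo-atom name CA so all downstream
    selections work unchanged.
    """

    chain_sizes: tuple[int, ...] = (20, 20)
    bridges: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    layout: str = "line"
    contact_spacing: float = 0.45
    bridge_distance: float = 0.45
    chain_gap: float = 0.85
    seed: int = 0


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def gen_toy_complex(spec: ToyComplexSpec) -> tuple[Topology, Trajectory]:
    """Build the bead complex and verify the realized contacts by distance scan.

    The designed contact set (consecutive beads within a chain for the line
    layout, all intra-chain pairs for clusters, plus the explicit bridges)
    must be exactly the set of bead pairs closer than 0.5 nm; any mismatch
    raises :class:`SpecError` (infeasible geometry).
    """
    cutoff = 0.5
    positions, designed = _layout_beads(spec, cutoff)
    records = []
    for c, size in enumerate(spec.chain_sizes):
        for r in range(size):
            records.append((_CHAIN_IDS[c], r + 1, "GLY",
                            [("CA", "C", positions[(c, r + 1)])]))
    top, coords = _build_topology(records)

    # verification scan: realized contacts must equal the design
    keys = list(positions.keys())
    realized = set()
    xyz = np.array([positions[k] for k in keys])
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if d[i, j] < cutoff:
                realized.add(frozenset((keys[i], keys[j])))
    if realized != designed:
        extra = realized - designed
        missing = designed - realized
        raise SpecError("infeasible toy-complex geometry: "
                        f"extra contacts {sorted(map(sorted, extra))}, "
                        f"missing {sorted(map(sorted, missing))}")
    traj = Trajectory(coords[None, :, :], np.array([0.0]), top)
    return top, traj


def _layout_beads(spec: ToyComplexSpec, cutoff: float):
    for (c1, r1), (c2, r2) in spec.bridges:
        for c, r in ((c1, r1), (c2, r2)):
            if c >= len(spec.chain_sizes) or not (1 <= r <= spec.chain_sizes[c]):
                raise SpecError(f"bridge references missing residue (chain {c}, resid {r})")
    s = spec.contact_spacing
    positions: dict[tuple[int, int], np.ndarray] = {}
    designed: set[frozenset] = set()
    if spec.layout == "line":
        # parallel vertical bead strings in the xy-plane, beads stacked in z
        for c, size in enumerate(spec.chain_sizes):
            for r in range(1, size + 1):
                positions[(c, r)] = np.array([spec.chain_gap * c, 0.0, s * (r - 1)])
                if r > 1:
                    designed.add(frozenset(((c, r - 1), (c, r))))
        for (c1, r1), (c2, r2) in spec.bridges:
            p1, p2 = positions[(c1, r1)], positions[(c2, r2)]
            mid_z = 0.5 * (p1[2] + p2[2])
            gap_dir = np.array([1.0 if c2 > c1 else -1.0, 0.0, 0.0])
            delta = 0.5 * (abs(c2 - c1) * spec.chain_gap - spec.bridge_distance)
            positions[(c1, r1)] = np.array([p1[0], 0.0, mid_z]) + delta * gap_dir
            positions[(c2, r2)] = np.array([p2[0], 0.0, mid_z]) - delta * gap_dir
            designed.add(frozenset(((c1, r1), (c2, r2))))
    elif spec.layout == "cluster":
        # each chain: equator ring of beads (radius rho) plus up to two
        # bridge beads at the +/-x poles; cluster centers spaced along x
        rho = 0.2
        center_gap = spec.bridge_distance + 2 * rho
        bridge_of: dict[int, list] = {c: [] for c in range(len(spec.chain_sizes))}
        for (c1, r1), (c2, r2) in spec.bridges:
            bridge_of[c1].append((r1, +1 if c2 > c1 else -1))
            bridge_of[c2].append((r2, +1 if c1 > c2 else -1))
        for c, size in enumerate(spec.chain_sizes):
            if len(bridge_of[c]) > 2:
                raise SpecError("cluster layout supports at most 2 bridges per chain")
            center = np.array([center_gap * c, 0.0, 0.0])
            pole_resids = {r for r, _ in bridge_of[c]}
            ring = [r for r in range(1, size + 1) if r not in pole_resids]
            for k, r in enumerate(ring):
                theta = 2.0 * np.pi * k / max(len(ring), 1)
                positions[(c, r)] = center + rho * np.array(
                    [0.0, np.cos(theta), np.sin(theta)])
            for r, direction in bridge_of[c]:
                positions[(c, r)] = center + np.array([direction * rho, 0.0, 0.0])
            for i in range(1, size + 1):
                for j in range(i + 1, size + 1):
                    designed.add(frozenset(((c, i), (c, j))))
        for (c1, r1), (c2, r2) in spec.bridges:
            if abs(c1 - c2) != 1:
                raise SpecError("cluster bridges must connect adjacent chains")
            designed.add(frozenset(((c1, r1), (c2, r2))))
    else:
        raise SpecError(f"unknown layout {spec.layout!r}")
    return positions, designed


# ---------------------------------------------------------------------------
# Multi-state ensembles
# ---------------------------------------------------------------------------

def gen_multistate_traj(k: int, per_state_frames: int, intra_spread: float,
                        inter_state_rmsd: float, seed: int = 0,
                        n_atoms: int = 10) -> tuple[Trajectory, np.ndarray]:
    """Frames jittering around ``k`` distinct conformers; returns ground-truth labels.

    Conformer s is the base structure displaced along a random (non-rigid)
    3N direction scaled so its RMSD from the base equals
    ``inter_state_rmsd``; each frame adds isotropic Gaussian jitter of
    ``intra_spread`` nm per coordinate.  States are separable when
    ``inter_state_rmsd > 5 * intra_spread``.
    """
    if k < 1 or per_state_frames < 1:
        raise SpecError("k and per_state_frames must be positive")
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_atoms, 3)) * 0.3
    conformers = [base]
    for _ in range(1, k):
        direction = rng.standard_normal((n_atoms, 3))
        direction -= direction.mean(axis=0)  # remove translation
        direction /= np.sqrt((direction ** 2).sum() / n_atoms)
        conformers.append(base + inter_state_rmsd * direction)
    frames, labels = [], []
    for s in range(k):
        jitter = rng.standard_normal((per_state_frames, n_atoms, 3)) * intra_spread
        frames.append(conformers[s][None] + jitter)
        labels.extend([s] * per_state_frames)
    coords = np.concatenate(frames, axis=0)
    times = np.arange(coords.shape[0], dtype=float)
    traj = Trajectory(coords, times, _point_topology(n_atoms))
    return traj, np.array(labels)


# ---------------------------------------------------------------------------
# Hydrogen-bond geometry fixture
# ---------------------------------------------------------------------------

def gen_hbond_fixture(donor_acceptor_distance: float,
                      hda_angle: float) -> tuple[Topology, Trajectory]:
    """Minimal N-H...O geometry with exact donor-acceptor distance (nm) and
    hydrogen-donor-acceptor angle (degrees, vertex at the donor)."""
    if donor_acceptor_distance <= 0:
        raise SpecError("distance must be positive")
    if not 0 <= hda_angle <= 180:
        raise SpecError("angle must be within [0, 180] degrees")
    d, a = donor_acceptor_distance, np.radians(hda_angle)
    n = np.array([0.0, 0.0, 0.0])
    o = np.array([d, 0.0, 0.0])
    h = _B_N_H * np.array([np.cos(a), np.sin(a), 0.0])
    records = [
        ("A", 1, "DON", [("N", "N", n), ("H", "H", h)]),
        ("A", 3, "ACC", [("O", "O", o)]),
    ]
    top, coords = _build_topology(records)
    top.bonds = [(0, 1)]
    from .structure import assign_donor_roles
    assign_donor_roles(top)
    traj = Trajectory(coords[None, :, :], np.array([0.0]), top)
    return top, traj
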