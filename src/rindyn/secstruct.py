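"""Kabsch-Sander-style secondary-structure assignment and timelines.

Backbone hydrogen bonds are scored with the classical electrostatic model
(E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332 kcal/mol, distances
in Angstrom; a bond exists when E < -0.5 kcal/mol) and turned into the
8-class alphabet H, G, I, E, B, T, S, C via n-turn and bridge patterns.
This is a re-implementation of the published definitions; byte-for-byte
agreement with any external assigner binary is not promised — correctness
is pinned by ideal-geometry fixtures.

Missing amide hydrogens are constructed as in :mod:`rindyn.hbond_sasa`.
Chain breaks (C-N distance > 0.25 nm) terminate all patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import angle_deg
from .errors import AnalysisError
from .structure import Topology, Trajectory
from .synth import amide_hydrogen

__all__ = [
    "SS_CLASSES",
    "SSAssignment",
    "ks_hbond_energy",
    "assign_ss",
    "ss_timeline",
]

SS_CLASSES = "HGIEBTSC"

_KS_Q = 0.084 * 332.0  # kcal/mol * Angstrom
_KS_CUTOFF = -0.5      # kcal/mol
_NM_TO_A = 10.0
_CHAIN_BREAK_NM = 0.25
_BEND_ANGLE_DEG = 70.0
_CA_FILTER_NM = 0.9    # pairs with CA-CA beyond this cannot hydrogen-bond


@dataclass
class SSAssignment:
    """Per-residue one-letter classes for one frame (protein residues only;
    non-protein residues carry '-')."""

    classes: np.ndarray  # dtype '<U1', length n_residues

    def counts(self) -> dict[str, int]:
        return {c: int(np.count_nonzero(self.classes == c)) for c in SS_CLASSES}


def ks_hbond_energy(donor_n, donor_h, acceptor_c, acceptor_o) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy (kcal/mol).

    Inputs are N and H coordinates of the donor residue and C and O of the
    acceptor residue, in nm.  A bond exists iff the energy is below
    -0.5 kcal/mol.  The formula is directional: swapping roles changes the
    energy.
    """
    r_on = np.linalg.norm(np.asarray(acceptor_o) - np.asarray(donor_n)) * _NM_TO_A
    r_ch = np.linalg.norm(np.asarray(acceptor_c) - np.asarray(donor_h)) * _NM_TO_A
    r_oh = np.linalg.norm(np.asarray(acceptor_o) - np.asarray(donor_h)) * _NM_TO_A
    r_cn = np.linalg.norm(np.asarray(acceptor_c) - np.asarray(donor_n)) * _NM_TO_A
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return -9.9e9  # overlapping atoms: clamp like the original
    return float(_KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


# ---------------------------------------------------------------------------
# backbone bookkeeping
# ---------------------------------------------------------------------------

def _backbone_table(topology: Topology, frame: np.ndarray):
    """Per protein residue: dict of N/CA/C/O/H coords (H built when absent),
    plus chain id and a residue->row map.  Returns (rows, index_of_residue)."""
    rows = []
    index_of = {}
    for ridx, res in enumerate(topology.residues):
        if not res.is_protein:
            continue
        names = {topology.atoms[i].name: i for i in res.atom_indices}
        entry = {"chain": res.chain_id, "residue_index": ridx}
        for a in ("N", "CA", "C", "O"):
            entry[a] = frame[names[a]] if a in names else None
        if "H" in names:
            entry["H"] = frame[names["H"]]
        else:
            entry["H"] = None
        index_of[ridx] = len(rows)
        rows.append(entry)
    # chain-break detection and H construction need sequence neighbors
    for k, row in enumerate(rows):
        prev = rows[k - 1] if k > 0 else None
        linked = (prev is not None and prev["chain"] == row["chain"]
                  and prev["C"] is not None and row["N"] is not None
                  and np.linalg.norm(row["N"] - prev["C"]) <= _CHAIN_BREAK_NM)
        row["linked_prev"] = linked
        if (row["H"] is None and linked and row["N"] is not None
                and row["CA"] is not None
                and topology.residues[row["residue_index"]].name != "PRO"):
            row["H"] = amide_hydrogen(row["N"], row["CA"], prev["C"])
    return rows


def _hbond_set(rows) -> set[tuple[int, int]]:
    """(donor_row, acceptor_row) pairs with K-S energy < -0.5 kcal/mol."""
    from scipy.spatial import cKDTree

    n = len(rows)
    cas = np.array([r["CA"] if r["CA"] is not None else [1e6, 1e6, 1e6] for r in rows])
    tree = cKDTree(cas)
    pairs = tree.query_pairs(_CA_FILTER_NM)
    bonds = set()
    for i, j in pairs:
        for d, a in ((i, j), (j, i)):
            rd, ra = rows[d], rows[a]
            if rd["N"] is None or rd["H"] is None:
                continue
            if ra["C"] is None or ra["O"] is None:
                continue
            # exclude self and sequence neighbors within a chain
            if d == a:
                continue
            if rd["chain"] == ra["chain"] and abs(d - a) < 2:
                continue
            e = ks_hbond_energy(rd["N"], rd["H"], ra["C"], ra["O"])
            if e < _KS_CUTOFF:
                bonds.add((d, a))
    return bonds


def _consecutive(rows, i, j) -> bool:
    """True if rows i..j (i<j) are sequence-consecutive without chain break."""
    if j >= len(rows):
        return False
    return all(rows[k]["linked_prev"] for k in range(i + 1, j + 1))


def assign_ss(frame: np.ndarray, topology: Topology) -> SSAssignment:
    """Assign one of H/G/I/E/B/T/S/C to every protein residue of one frame.

    n-turns (n = 3, 4, 5) come from hbond(i+n -> i); two consecutive
    n-turns make a helix (class priority H > G > I on overlap); Kabsch-
    Sander parallel/antiparallel bridge patterns make B, with runs of >= 2
    consecutive bridges promoted to E; a single n-turn marks T; a bend S is
    assigned where the CA(i-2)..CA(i)..CA(i+2) direction change exceeds
    70 degrees; everything else is coil C.
    """
    frame = np.asarray(frame, dtype=float)
    rows = _backbone_table(topology, frame)
    n = len(rows)
    classes = np.full(topology.n_residues, "-", dtype="<U1")
    for row in rows:
        classes[row["residue_index"]] = "C"
    if n == 0:
        return SSAssignment(classes)

    bonds = _hbond_set(rows)

    def turn(nlen, i):
        return (i + nlen, i) in bonds and _consecutive(rows, i, i + nlen)

    turns = {nlen: {i for i in range(n) if turn(nlen, i)} for nlen in (3, 4, 5)}

    helix_members = {3: set(), 4: set(), 5: set()}
    for nlen in (3, 4, 5):
        for i in turns[nlen]:
            if i + 1 in turns[nlen]:
                helix_members[nlen].update(range(i + 1, i + nlen + 1))

    def hb(d, a):
        return (d, a) in bonds

    def seq_ok(i):
        return 0 <= i < n

    bridge = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if rows[i]["chain"] == rows[j]["chain"] and abs(i - j) < 3:
                continue
            par = False
            if seq_ok(i - 1) and seq_ok(i + 1) and _consecutive(rows, i - 1, i + 1):
                par = (hb(j, i - 1) and hb(i + 1, j))
            if not par and seq_ok(j - 1) and seq_ok(j + 1) and _consecutive(rows, j - 1, j + 1):
                par = (hb(i, j - 1) and hb(j + 1, i))
            anti = hb(i, j) and hb(j, i)
            if not anti and seq_ok(i - 1) and seq_ok(i + 1) and seq_ok(j - 1) and seq_ok(j + 1):
                if _consecutive(rows, i - 1, i + 1) and _consecutive(rows, j - 1, j + 1):
                    anti = hb(j + 1, i - 1) and hb(i + 1, j - 1)
            if par or anti:
                bridge.add((i, j))

    bridge_res = {i for i, _ in bridge}
    sheet_res = set()
    for i in bridge_res:
        if ((i - 1 in bridge_res and _consecutive(rows, i - 1, i))
                or (i + 1 in bridge_res and _consecutive(rows, i, i + 1))):
            sheet_res.add(i)

    turn_res = set()
    for nlen in (3, 4, 5):
        for i in turns[nlen]:
            turn_res.update(range(i + 1, i + nlen))

    bend_res = set()
    for k in range(2, n - 2):
        if not _consecutive(rows, k - 2, k + 2):
            continue
        ca_m2, ca_0, ca_p2 = rows[k - 2]["CA"], rows[k]["CA"], rows[k + 2]["CA"]
        if ca_m2 is None or ca_0 is None or ca_p2 is None:
            continue
        # direction change of the chain at k
        kink = 180.0 - angle_deg(ca_m2, ca_0, ca_p2)
        if kink > _BEND_ANGLE_DEG:
            bend_res.add(k)

    for k, row in enumerate(rows):
        if k in helix_members[4]:
            c = "H"
        elif k in sheet_res:
            c = "E"
        elif k in bridge_res:
            c = "B"
        elif k in helix_members[3]:
            c = "G"
        elif k in helix_members[5]:
            c = "I"
        elif k in turn_res:
            c = "T"
        elif k in bend_res:
            c = "S"
        else:
            c = "C"
        classes[row["residue_index"]] = c
    return SSAssignment(classes)


def ss_timeline(traj: Trajectory, topology: Topology | None = None):
    """Per-frame class counts and the residue x frame class matrix.

    Returns ``(counts, matrix)`` where ``counts`` is a pandas DataFrame
    (frames x 8 classes; counts sum to the protein residue count every
    frame) and ``matrix`` is an (n_frames, n_residues) array of one-letter
    codes ('-' for non-protein residues).
    """
    import pandas as pd

    top = topology or traj.topology
    if traj.n_frames < 1:
        raise AnalysisError("timeline requires at least one frame")
    matrix = np.full((traj.n_frames, top.n_residues), "-", dtype="<U1")
    counts = np.zeros((traj.n_frames, len(SS_CLASSES)), dtype=int)
    for f in range(traj.n_frames):
        assignment = assign_ss(traj.coordinates[f], top)
        matrix[f] = assignment.classes
        for c, cls in enumerate(SS_CLASSES):
            counts[f, c] = int(np.count_nonzero(assignment.classes == cls))
    frame_index = pd.Index(traj.times, name="time_ps")
    return pd.DataFrame(counts, index=frame_index, columns=list(SS_CLASSES)), matrix


def timeline_to_tsv(matrix: np.ndarray, path) -> None:
    """Write the residue x frame class matrix as TSV (one row per frame)."""
    with open(path, "w") as fh:
        for f in range(matrix.shape[0]):
            fh.write("".join(matrix[f]) + "\n")
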