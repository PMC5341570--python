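"""Molecular structures and trajectories: containers, PDB I/O, selection, bonds.

The in-memory model is deliberately small: a static :class:`Topology`
(atoms, residues, chains, bonds) and a :class:`Trajectory` holding an
``(n_frames, n_atoms, 3)`` coordinate array in nanometres with per-frame
times in picoseconds.  PDB files are parsed and written through biotite;
coordinates are converted Angstrom <-> nm only at the file boundary.

Residue numbering is always the author numbering as deposited (never
renumbered); frame indices are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGSTROM_PER_NM,
    BACKBONE_ATOMS,
    DISULFIDE_CUTOFF_NM,
    HEAVY_HEAVY_BOND_CUTOFF_NM,
    HYDROGEN_BOND_LENGTH_CUTOFF_NM,
    PEPTIDE_BOND_CUTOFF_NM,
    STANDARD_AMINO_ACIDS,
    WATER_RESIDUES,
    mass_of,
)
from .errors import FormatError, PDBParseError, SelectionError

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_frames",
    "write_frames",
    "select_atoms",
    "perceive_bonds",
    "assign_donor_roles",
]


@dataclass
class Atom:
    """One atom of the static topology.

    ``donor_role`` is one of ``"none"``, ``"donor-heavy"`` (N/O carrying at
    least one bonded hydrogen) or ``"acceptor"``; it is filled in by
    :func:`assign_donor_roles` once bonds are known.  Coordinates live in the
    :class:`Trajectory`, not here.
    """

    name: str
    element: str
    residue_index: int
    is_heavy: bool = True
    donor_role: str = "none"

    def __post_init__(self):
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if self.element.upper() in ("H", "D") and self.is_heavy:
            raise ValueError("hydrogen atoms must have is_heavy=False")


@dataclass
class Residue:
    """One residue: 3-letter name, author seq id, chain, atom membership."""

    name: str
    seq_id: int
    chain_id: str
    atom_indices: list[int] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False
    is_water: bool = False

    @property
    def is_protein(self) -> bool:
        return self.name in STANDARD_AMINO_ACIDS

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, seq_id, insertion_code) — unique within a topology."""
        return (self.chain_id, self.seq_id, self.insertion_code)

    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_id}{self.insertion_code}"


class Topology:
    """Static molecular description: atom and residue tables, chains, bonds."""

    def __init__(self, atoms: list[Atom], residues: list[Residue],
                 bonds: list[tuple[int, int]] | None = None):
        self.atoms = atoms
        self.residues = residues
        self.bonds: list[tuple[int, int]] = [] if bonds is None else list(bonds)
        seen = set()
        self.chains: list[str] = []
        for res in residues:
            if res.chain_id not in seen:
                seen.add(res.chain_id)
                self.chains.append(res.chain_id)
        keys = [r.key for r in residues]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (chain, seq_id, insertion_code) residue keys")
        self._cache: dict[str, np.ndarray] = {}

    # -- vectorised views -------------------------------------------------

    def _arr(self, key, build):
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def atom_names(self) -> np.ndarray:
        return self._arr("names", lambda: np.array([a.name for a in self.atoms]))

    @property
    def elements(self) -> np.ndarray:
        return self._arr("elements",
                         lambda: np.array([a.element.upper() for a in self.atoms]))

    @property
    def atom_residue_index(self) -> np.ndarray:
        return self._arr("resix",
                         lambda: np.array([a.residue_index for a in self.atoms]))

    @property
    def is_heavy(self) -> np.ndarray:
        return self._arr("heavy", lambda: np.array([a.is_heavy for a in self.atoms]))

    @property
    def masses(self) -> np.ndarray:
        return self._arr("masses",
                         lambda: np.array([mass_of(a.element) for a in self.atoms]))

    def residue_of(self, atom_index: int) -> Residue:
        return self.residues[self.atoms[atom_index].residue_index]

    def invalidate_caches(self) -> None:
        self._cache.clear()

    # -- bonds ------------------------------------------------------------

    def bonded_neighbors(self) -> list[set[int]]:
        nb: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            nb[i].add(j)
            nb[j].add(i)
        return nb

    def validate(self) -> None:
        n = self.n_atoms
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise FormatError(f"bond ({i},{j}) references invalid atom index")


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates in nm with strictly increasing times (ps)."""

    coordinates: np.ndarray
    times: np.ndarray
    topology: Topology

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] != self.times.shape[0]:
            raise FormatError("times length must match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("frame times must be strictly increasing")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise FormatError("atom count mismatch between coordinates and topology")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, index: int) -> np.ndarray:
        return self.coordinates[index]

    def slice_frames(self, start=None, stop=None, step=None) -> "Trajectory":
        sl = slice(start, stop, step)
        return Trajectory(self.coordinates[sl].copy(), self.times[sl].copy(),
                          self.topology)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _topology_from_atom_array(array) -> Topology:
    import biotite.structure as struc

    elements = np.asarray(array.element)
    blank = np.array([e.strip() == "" for e in elements])
    if blank.any():
        inferred = struc.infer_elements(array)
        elements = np.where(blank, inferred, elements)

    atoms: list[Atom] = []
    residues: list[Residue] = []
    last_key = None
    for i in range(array.array_length()):
        ins = str(array.ins_code[i]).strip() if "ins_code" in array.get_annotation_categories() else ""
        key = (str(array.chain_id[i]), int(array.res_id[i]), ins, str(array.res_name[i]))
        if key != last_key:
            name = str(array.res_name[i])
            residues.append(Residue(
                name=name,
                seq_id=int(array.res_id[i]),
                chain_id=str(array.chain_id[i]),
                insertion_code=ins,
                is_hetero=bool(array.hetero[i]),
                is_water=name in WATER_RESIDUES,
            ))
            last_key = key
        res_index = len(residues) - 1
        el = str(elements[i]).upper()
        atoms.append(Atom(
            name=str(array.atom_name[i]),
            element=el,
            residue_index=res_index,
            is_heavy=el not in ("H", "D"),
        ))
        residues[res_index].atom_indices.append(i)
    return Topology(atoms, residues)


def read_structure(path, fmt: str = "pdb") -> tuple[Topology, Trajectory]:
    """Read a structure file into ``(Topology, Trajectory)``.

    Multi-MODEL PDB files yield one frame per MODEL (all models must share
    the same atoms).  Coordinates are converted Angstrom -> nm.  Author chain
    IDs, residue numbers and insertion codes are preserved verbatim; HETATM
    groups are retained but flagged, waters are flagged as such.  Highest-
    occupancy altloc conformers are kept (ties -> first encountered).

    Parameters
    ----------
    path : str or Path
        File to read.
    fmt : {"pdb", "frames"}
        ``"pdb"`` for PDB files; ``"frames"`` for the plain-text coordinate
        format (see :func:`read_frames`, which needs an explicit topology).
    """
    if fmt != "pdb":
        raise FormatError(f"unsupported structure format {fmt!r}")
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        msg = str(exc)
        if "atoms" in msg.lower() and ("model" in msg.lower() or "equal" in msg.lower()):
            raise FormatError(f"{path}: inconsistent atom count across MODELs: {msg}") from exc
        raise PDBParseError(f"{path}: {msg}") from exc

    topology = _topology_from_atom_array(stack[0])
    coords_nm = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
    n_frames = coords_nm.shape[0]
    times = np.arange(n_frames, dtype=float)
    traj = Trajectory(coords_nm, times, topology)
    return topology, traj


def write_structure(path, topology: Topology, trajectory: Trajectory) -> None:
    """Write a (possibly multi-frame) structure as a PDB file (nm -> Angstrom)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n_frames, n_atoms = trajectory.n_frames, trajectory.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = trajectory.coordinates * ANGSTROM_PER_NM
    chain_ids, res_ids, ins, res_names, het = [], [], [], [], []
    for atom in topology.atoms:
        res = topology.residues[atom.residue_index]
        chain_ids.append(res.chain_id)
        res_ids.append(res.seq_id)
        ins.append(res.insertion_code)
        res_names.append(res.name)
        het.append(res.is_hetero)
    stack.chain_id = np.array(chain_ids)
    stack.res_id = np.array(res_ids)
    stack.ins_code = np.array(ins)
    stack.res_name = np.array(res_names)
    stack.hetero = np.array(het)
    stack.atom_name = topology.atom_names
    stack.element = topology.elements
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Plain-text frame format
# ---------------------------------------------------------------------------
# Each frame: a header line "natoms time_ps" followed by natoms lines "x y z"
# in nm.  Useful for shipping synthetic trajectories as small text fixtures.

def write_frames(path, trajectory: Trajectory) -> None:
    """Write trajectory coordinates in the plain-text frame format (nm)."""
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms} {trajectory.times[f]:.6f}\n")
            for x, y, z in trajectory.coordinates[f]:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_frames(path, topology: Topology) -> Trajectory:
    """Read the plain-text frame format written by :func:`write_frames`."""
    coords, times = [], []
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    pos = 0
    while pos < len(lines):
        parts = lines[pos].split()
        if len(parts) != 2:
            raise PDBParseError(f"{path}: bad frame header at line {pos + 1}")
        natoms, t = int(parts[0]), float(parts[1])
        if natoms != topology.n_atoms:
            raise FormatError(
                f"{path}: frame atom count {natoms} != topology {topology.n_atoms}")
        block = lines[pos + 1: pos + 1 + natoms]
        if len(block) < natoms:
            raise PDBParseError(f"{path}: truncated frame starting at line {pos + 1}")
        coords.append([[float(v) for v in ln.split()] for ln in block])
        times.append(t)
        pos += 1 + natoms
    return Trajectory(np.array(coords), np.array(times), topology)


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_KEYWORDS = {"name", "element", "chain", "resid", "resname", "backbone", "calpha",
             "heavy", "protein", "water", "hetero", "all", "none",
             "and", "or", "not", "(", ")"}

_OPERATORS = {"and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    expression = expression.replace("(", " ( ").replace(")", " ) ")
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


class _SelectionParser:
    """Recursive-descent parser for the small selection grammar.

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := "not" factor | "(" expr ")" | primary
    primary := keyword [value ...]
    """

    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _OPERATORS:
            nxt = self.peek()
            if nxt in _KEYWORDS and nxt not in ("to",):
                break
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword requires at least one value")
        return vals

    def primary(self) -> np.ndarray:
        top = self.top
        tok = self.take()
        n = top.n_atoms
        res_idx = top.atom_residue_index
        if tok == "all":
            return np.ones(n, bool)
        if tok == "none":
            return np.zeros(n, bool)
        if tok == "backbone":
            return np.isin(top.atom_names, BACKBONE_ATOMS) & self._residue_mask(
                lambda r: r.is_protein)
        if tok == "calpha":
            return (top.atom_names == "CA") & self._residue_mask(lambda r: r.is_protein)
        if tok == "heavy":
            return top.is_heavy.copy()
        if tok == "protein":
            return self._residue_mask(lambda r: r.is_protein)
        if tok == "water":
            return self._residue_mask(lambda r: r.is_water)
        if tok == "hetero":
            return self._residue_mask(lambda r: r.is_hetero)
        if tok == "name":
            return np.isin(top.atom_names, self._values())
        if tok == "element":
            return np.isin(top.elements, [v.upper() for v in self._values()])
        if tok == "chain":
            chains = set(self._values())
            return self._residue_mask(lambda r: r.chain_id in chains)
        if tok == "resname":
            names = set(v.upper() for v in self._values())
            return self._residue_mask(lambda r: r.name in names)
        if tok == "resid":
            ids = self._resid_values()
            return self._residue_mask(lambda r: r.seq_id in ids)
        raise SelectionError(f"unknown selection token {tok!r}")

    def _resid_values(self) -> set[int]:
        vals = self._values()
        ids: set[int] = set()
        i = 0
        while i < len(vals):
            v = vals[i]
            if i + 2 < len(vals) and vals[i + 1] == "to":
                lo, hi = self._int(v), self._int(vals[i + 2])
                ids.update(range(lo, hi + 1))
                i += 3
                continue
            m = re.fullmatch(r"(-?\d+):(-?\d+)", v)
            if m:
                ids.update(range(int(m.group(1)), int(m.group(2)) + 1))
            else:
                ids.add(self._int(v))
            i += 1
        return ids

    @staticmethod
    def _int(tok: str) -> int:
        try:
            return int(tok)
        except ValueError:
            raise SelectionError(f"expected residue number, got {tok!r}") from None

    def _residue_mask(self, predicate) -> np.ndarray:
        res_flags = np.array([predicate(r) for r in self.top.residues])
        return res_flags[self.top.atom_residue_index]


def select_atoms(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning sorted unique atom indices.

    Grammar: ``name``/``element``/``resname``/``chain`` followed by one or
    more values, ``resid`` with numbers, ``lo:hi`` ranges or ``lo to hi``,
    the flags ``backbone``, ``calpha``, ``heavy``, ``protein``, ``water``,
    ``hetero``, ``all``, ``none``, combined with ``and`` / ``or`` / ``not``
    and parentheses.  An empty result is allowed.

    >>> select_atoms(top, "chain A and resid 299")      # doctest: +SKIP
    """
    tokens = _tokenize(expression)
    mask = _SelectionParser(tokens, topology).parse()
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def _template_bonds(res: Residue, name_to_index: dict[str, int]) -> list[tuple[int, int]] | None:
    """Intra-residue bonds from the chemical-component template, or None."""
    try:
        from biotite.structure.info import bonds_in_residue
        template = bonds_in_residue(res.name)
    except KeyError:
        return None
    if not template:
        return None
    bonds = []
    for (a, b) in template:
        ia, ib = name_to_index.get(a), name_to_index.get(b)
        if ia is not None and ib is not None:
            bonds.append((min(ia, ib), max(ia, ib)))
    return bonds


def _distance_bonds(res: Residue, topology: Topology, frame: np.ndarray) -> list[tuple[int, int]]:
    """Distance-criterion fallback for residues without a template."""
    idx = res.atom_indices
    heavy = [i for i in idx if topology.atoms[i].is_heavy]
    hydro = [i for i in idx if not topology.atoms[i].is_heavy]
    bonds = []
    for ai in range(len(heavy)):
        for aj in range(ai + 1, len(heavy)):
            i, j = heavy[ai], heavy[aj]
            if np.linalg.norm(frame[i] - frame[j]) < HEAVY_HEAVY_BOND_CUTOFF_NM:
                bonds.append((min(i, j), max(i, j)))
    for h in hydro:
        if not heavy:
            continue
        d = np.linalg.norm(frame[heavy] - frame[h], axis=1)
        k = int(np.argmin(d))
        if d[k] < HYDROGEN_BOND_LENGTH_CUTOFF_NM:
            i, j = heavy[k], h
            bonds.append((min(i, j), max(i, j)))
    return bonds


def perceive_bonds(topology: Topology, frame: np.ndarray) -> list[tuple[int, int]]:
    """Perceive covalent bonds from one coordinate frame (nm).

    Intra-residue bonds come from standard amino-acid templates (chemical
    component dictionary); residues without a template fall back to a
    distance criterion (heavy-heavy < 0.19 nm; H attached to nearest heavy
    < 0.12 nm).  Inter-residue peptide bonds are added between consecutive
    residues of the same chain when the C(i)-N(i+1) distance is < 0.19 nm,
    and disulfide bridges when two SG atoms are closer than 0.25 nm.
    Unbondable atoms simply remain unbonded.
    """
    frame = np.asarray(frame, dtype=float)
    bonds: set[tuple[int, int]] = set()
    for res in topology.residues:
        name_to_index = {topology.atoms[i].name: i for i in res.atom_indices}
        tbonds = _template_bonds(res, name_to_index)
        if tbonds is None:
            tbonds = _distance_bonds(res, topology, frame)
        bonds.update(tbonds)

    # peptide bonds between consecutive residues of the same chain
    for ri in range(len(topology.residues) - 1):
        r1, r2 = topology.residues[ri], topology.residues[ri + 1]
        if r1.chain_id != r2.chain_id:
            continue
        c = next((i for i in r1.atom_indices if topology.atoms[i].name == "C"), None)
        n = next((i for i in r2.atom_indices if topology.atoms[i].name == "N"), None)
        if c is None or n is None:
            continue
        if np.linalg.norm(frame[c] - frame[n]) < PEPTIDE_BOND_CUTOFF_NM:
            bonds.add((min(c, n), max(c, n)))

    # disulfides
    sg = [i for i, a in enumerate(topology.atoms)
          if a.name == "SG" and topology.residues[a.residue_index].name in ("CYS", "CYX")]
    for ai in range(len(sg)):
        for aj in range(ai + 1, len(sg)):
            i, j = sg[ai], sg[aj]
            if topology.atoms[i].residue_index == topology.atoms[j].residue_index:
                continue
            if np.linalg.norm(frame[i] - frame[j]) < DISULFIDE_CUTOFF_NM:
                bonds.add((min(i, j), max(i, j)))

    return sorted(bonds)


def assign_donor_roles(topology: Topology) -> None:
    """Fill ``Atom.donor_role`` from element identity and bonded hydrogens.

    N and O atoms are acceptors; those carrying at least one covalently
    bonded hydrogen are marked as heavy donor atoms (OH and NH groups
    donate).  Requires ``topology.bonds`` to be populated.
    """
    neighbors = topology.bonded_neighbors()
    for i, atom in enumerate(topology.atoms):
        el = atom.element.upper()
        if el not in ("N", "O"):
            atom.donor_role = "none"
            continue
        has_h = any(not topology.atoms[j].is_heavy for j in neighbors[i])
        atom.donor_role = "donor-heavy" if has_h else "acceptor"
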