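"""Low-level geometry: internal-coordinate atom placement, angles, dihedrals."""

from __future__ import annotations

import numpy as np

from .errors import AnalysisError


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise AnalysisError("cannot normalise zero vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees (vertex at b)."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, range (-180, 180].

    Standard atan2 construction; raises for collinear inner triples.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise AnalysisError("undefined dihedral: collinear atom triple")
    b1n = b1 / np.linalg.norm(b1)
    m1 = np.cross(n1, b1n)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given three predecessors (NeRF construction).

    ``bond`` = |C-D|, ``angle`` = B-C-D in degrees, ``dihedral`` = A-B-C-D in
    degrees.  All lengths in the caller's unit.
    """
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(dih),
        -np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
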