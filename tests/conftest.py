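import numpy as np
import pytest

from rindyn.structure import Atom, Residue, Topology, Trajectory
from rindyn.synth import ToyComplexSpec, gen_ideal_secondary, gen_toy_complex


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue alpha helix (topology, single-frame trajectory)."""
    return gen_ideal_secondary("alpha_helix", 12)


@pytest.fixture(scope="session")
def sheet6():
    """Two H-bonded antiparallel 6-residue strands."""
    return gen_ideal_secondary("antiparallel_sheet", 6)


@pytest.fixture(scope="session")
def two_chain_bridge():
    """Two 20-bead chains with a single designed inter-chain contact."""
    spec = ToyComplexSpec(chain_sizes=(20, 20), bridges=[((0, 10), (1, 10))])
    return gen_toy_complex(spec)


def point_topology(n):
    """Bare one-atom-per-residue topology for coordinate-level tests."""
    atoms = [Atom(f"C{i}", "C", i) for i in range(n)]
    residues = [Residue("LIG", i + 1, "A", [i]) for i in range(n)]
    return Topology(atoms, residues)


def point_trajectory(coords, times=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(coords, times, point_topology(coords.shape[1]))
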