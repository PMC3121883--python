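import numpy as np
import pytest

from pepmd import (
    Atom,
    AtomSelection,
    Frame,
    Trajectory,
    reference_peptide_frames,
)


@pytest.fixture(scope="session")
def ref_frames() -> dict[str, Frame]:
    """The four idealized bound-peptide conformations (shared topology)."""
    return reference_peptide_frames()


@pytest.fixture(scope="session")
def peptide_topology(ref_frames):
    return ref_frames["hairpin"].topology


def make_point_topology(n: int, chain_id: str = "X") -> tuple[Atom, ...]:
    """n pseudo-atoms (one CA per residue) for geometry-only tests."""
    return tuple(
        Atom(name="CA", residue_name="GLY", residue_id=i + 1, chain_id=chain_id,
             element="C", mass=12.011)
        for i in range(n)
    )


@pytest.fixture
def point_topology():
    return make_point_topology(10)


def make_trajectory(coords: np.ndarray, topology=None, dt: float = 1.0) -> Trajectory:
    coords = np.asarray(coords, float)
    if topology is None:
        topology = make_point_topology(coords.shape[1])
    return Trajectory(topology, coords, dt=dt)


@pytest.fixture
def all_atom_selection():
    return AtomSelection()
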