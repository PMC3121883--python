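"""Structure and trajectory I/O.

Multi-model PDB is the native, test-covered exchange format: MODEL records
map to frames in file order, with an identical atom order in every model.
Parsing and formatting are delegated to biotite; this module adds the
Trajectory contract, validation and error reporting on top.
"""

from __future__ import annotations

import logging
from os import PathLike
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import Atom, Trajectory
from .errors import ParseError, StructureError

__all__ = ["read_structure", "write_structure"]

logger = logging.getLogger(__name__)

_COORD_FIELDS = ((30, 38), (38, 46), (46, 54))


def _validate_pdb_lines(path: Path) -> None:
    """Pre-scan coordinate records so parse errors can name the line."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}, line {lineno}: truncated coordinate record")
            for start, stop in _COORD_FIELDS:
                try:
                    float(line[start:stop])
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: malformed coordinate field "
                        f"{line[start:stop]!r}"
                    ) from None


def read_structure(
    path: str | PathLike,
    format: str = "pdb",
    dt: float = 1.0,
    altloc: str = "first",
) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Frame times are synthesized as ``i * dt`` (PDB stores no times).
    Alternate locations other than the first are dropped with a warning.
    """
    if format != "pdb":
        raise ParseError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    _validate_pdb_lines(path)
    try:
        pdb_file = PDBFile.read(path)
        stack = pdb_file.get_structure(model=None, altloc=altloc)
    except Exception as exc:  # biotite raises InvalidFileError / ValueError
        msg = str(exc)
        if "must be equal" in msg or "atoms" in msg:
            raise StructureError(f"{path}: inconsistent models: {msg}") from exc
        raise ParseError(f"{path}: {msg}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    if "A" in np.unique(getattr(stack, "altloc_id", np.array([]))):
        logger.warning("%s: alternate locations present; keeping first altloc only", path)

    elements = stack.element
    blank = np.array([e == "" for e in elements])
    if blank.any():
        elements = np.asarray(struc.infer_elements(stack.atom_name))

    topology = []
    for i in range(stack.array_length()):
        element = str(elements[i]).capitalize()
        try:
            from biotite.structure.info import mass as _mass

            m = _mass(element)
        except Exception:
            m = None
        if m is None or m <= 0:
            logger.warning("unknown element %r for atom %s; assuming mass 1.0", element, i)
            m = 1.0
        topology.append(
            Atom(
                name=str(stack.atom_name[i]),
                residue_name=str(stack.res_name[i]),
                residue_id=int(stack.res_id[i]),
                chain_id=str(stack.chain_id[i]),
                element=element,
                mass=float(m),
            )
        )
    coords = np.asarray(stack.coord, dtype=float)
    return Trajectory(topology, coords, dt=dt)


def write_structure(traj: Trajectory, path: str | PathLike, format: str = "pdb") -> None:
    """Write a :class:`Trajectory` as a (multi-model) PDB file.

    A single-frame trajectory is written without MODEL records; multi-frame
    trajectories get one MODEL/ENDMDL block per frame.  Coordinates are
    fixed-width with 3 decimals (PDB precision, 1e-3 Å round-trip).
    """
    if format != "pdb":
        raise ParseError(f"unsupported structure format {format!r}")
    n_atoms = traj.n_atoms
    array = struc.AtomArray(n_atoms)
    array.coord = np.asarray(traj.coords[0], dtype=np.float32)
    array.atom_name = np.array([a.name for a in traj.topology], dtype="U6")
    array.res_name = np.array([a.residue_name for a in traj.topology], dtype="U5")
    array.res_id = np.array([a.residue_id for a in traj.topology], dtype=int)
    array.chain_id = np.array([a.chain_id for a in traj.topology], dtype="U4")
    array.element = np.array([a.element for a in traj.topology], dtype="U2")
    array.set_annotation("occupancy", np.ones(n_atoms, dtype=float))
    array.set_annotation("b_factor", np.zeros(n_atoms, dtype=float))

    pdb_file = PDBFile()
    if traj.n_frames == 1:
        pdb_file.set_structure(array)
    else:
        stack = struc.stack([array] * traj.n_frames)
        stack.coord = np.asarray(traj.coords, dtype=np.float32)
        pdb_file.set_structure(stack)
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise ParseError(f"cannot write {path}: {exc}") from exc
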