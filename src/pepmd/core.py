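"""Core domain types: atoms, frames and trajectories.

Unit conventions used throughout the package:

* coordinates and distances in Angstrom (Å)
* times in picoseconds (ps)
* energies in kcal/mol
* temperatures in Kelvin
* masses in atomic mass units
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import StructureError

__all__ = ["Atom", "Frame", "Trajectory"]


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``(chain_id, residue_id, name)`` must be unique within a structure;
    this triple is used as the atom key everywhere in the package.
    """

    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str = ""
    mass: float = 1.0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_id, self.name)

    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.residue_id}:{self.name}"


def _validate_topology(topology: Sequence[Atom]) -> None:
    if len(topology) == 0:
        raise StructureError("topology is empty")
    seen: set[tuple[str, int, str]] = set()
    for atom in topology:
        if atom.mass <= 0:
            raise StructureError(f"atom {atom.label()} has non-positive mass {atom.mass}")
        if atom.key in seen:
            raise StructureError(f"duplicate atom key {atom.key}")
        seen.add(atom.key)


@dataclass(frozen=True)
class Frame:
    """One coordinate set (Å) over a fixed topology, at time ``time`` (ps)."""

    topology: tuple[Atom, ...]
    coords: np.ndarray  # (n_atoms, 3), Å
    time: float = 0.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.topology), 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.topology)} topology atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology], dtype=float)


class Trajectory:
    """Time-ordered coordinate sets over one topology.

    Parameters
    ----------
    topology:
        Ordered atoms; order is identical across frames.
    coords:
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    dt:
        Spacing between stored frames in ps. Ignored when explicit ``times``
        are given, in which case it is inferred (and checked for consistency
        within 1e-6 ps).
    times:
        Optional explicit frame times in ps, strictly increasing.
    """

    def __init__(
        self,
        topology: Sequence[Atom],
        coords: np.ndarray,
        dt: float | None = None,
        times: Sequence[float] | None = None,
    ) -> None:
        _validate_topology(topology)
        self.topology: tuple[Atom, ...] = tuple(topology)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError(f"coordinates must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[1] != len(self.topology):
            raise StructureError(
                f"{coords.shape[1]} coordinates per frame but {len(self.topology)} topology atoms"
            )
        if coords.shape[0] == 0:
            raise StructureError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates in trajectory")
        self.coords = coords

        if times is not None:
            times_arr = np.asarray(times, dtype=float)
            if times_arr.shape != (coords.shape[0],):
                raise StructureError("one time per frame required")
            if len(times_arr) > 1:
                diffs = np.diff(times_arr)
                if np.any(diffs <= 0):
                    raise StructureError("frame times must be strictly increasing")
                inferred = float(diffs[0])
                if dt is None:
                    dt = inferred
                if np.any(np.abs(diffs - dt) > 1e-6):
                    raise StructureError(
                        f"frame times inconsistent with dt={dt} ps (beyond 1e-6 ps)"
                    )
            elif dt is None:
                dt = 1.0
            self.times = times_arr
        else:
            if dt is None:
                dt = 1.0
            if dt <= 0:
                raise StructureError(f"dt must be positive, got {dt}")
            self.times = np.arange(coords.shape[0], dtype=float) * dt
        if dt <= 0:
            raise StructureError(f"dt must be positive, got {dt}")
        self.dt = float(dt)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, index: int) -> Frame:
        return Frame(self.topology, self.coords[index], time=float(self.times[index]))

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, index: int) -> Frame:
        return self.frame(index)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], dt: float | None = None) -> "Trajectory":
        if not frames:
            raise StructureError("no frames given")
        topology = frames[0].topology
        for f in frames[1:]:
            if f.topology != topology:
                raise StructureError("all frames must share one topology")
        coords = np.stack([f.coords for f in frames])
        times = [f.time for f in frames]
        if len(frames) > 1 and times[-1] > times[0]:
            return cls(topology, coords, dt=dt, times=times)
        return cls(topology, coords, dt=dt)
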