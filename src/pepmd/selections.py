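"""Declarative atom selections and the C-terminal position numbering map.

Peptide residues are labelled by their position relative to the C-terminus
(position 0 is the last residue, -1 the one before it, ...), the standard
convention for PDZ-binding peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Atom
from .errors import SelectionError

__all__ = [
    "BACKBONE",
    "BACKBONE_WITH_O",
    "AtomSelection",
    "PeptidePositionMap",
    "resolve_selection",
]

# Mainchain heavy atoms excluding the carbonyl oxygen; matches the GROMOS/
# GROMACS "backbone" group convention.  Use BACKBONE_WITH_O to include O.
BACKBONE = frozenset({"N", "CA", "C"})
BACKBONE_WITH_O = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class AtomSelection:
    """A declarative subset of atoms.

    Each criterion that is ``None`` matches everything; a non-None criterion
    must match exactly.  ``residue_ids`` may be paired with ``chain_ids`` to
    disambiguate identical numbering across chains.
    """

    chain_ids: frozenset[str] | None = None
    residue_ids: tuple[int, ...] | None = None
    atom_names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.chain_ids is not None:
            object.__setattr__(self, "chain_ids", frozenset(self.chain_ids))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if self.residue_ids is not None:
            object.__setattr__(self, "residue_ids", tuple(self.residue_ids))

    def matches(self, atom: Atom) -> bool:
        if self.chain_ids is not None and atom.chain_id not in self.chain_ids:
            return False
        if self.residue_ids is not None and atom.residue_id not in self.residue_ids:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True

    def resolve(self, topology: Sequence[Atom]) -> np.ndarray:
        return resolve_selection(self, topology)

    def describe(self) -> str:
        parts = []
        if self.chain_ids is not None:
            parts.append(f"chain_ids={sorted(self.chain_ids)}")
        if self.residue_ids is not None:
            parts.append(f"residue_ids={list(self.residue_ids)}")
        if self.atom_names is not None:
            parts.append(f"atom_names={sorted(self.atom_names)}")
        return ", ".join(parts) if parts else "<all atoms>"


def resolve_selection(sel: AtomSelection, topology: Sequence[Atom]) -> np.ndarray:
    """Resolve ``sel`` against ``topology`` into an ordered index array.

    Indices follow topology order and the result is a pure function of
    ``(sel, topology)``.  An empty result raises :class:`SelectionError`
    naming the unmatched criteria.
    """
    if len(topology) == 0:
        raise SelectionError("cannot resolve a selection against an empty topology")
    idx = np.array([i for i, a in enumerate(topology) if sel.matches(a)], dtype=np.intp)
    if idx.size == 0:
        raise SelectionError(f"selection matched no atoms ({sel.describe()})")
    return idx


class PeptidePositionMap:
    """Maps C-terminal position labels (0, -1, -2, ...) to (chain, residue id).

    Position 0 is the chain's last residue; labels decrease by one walking
    toward the N-terminus.
    """

    def __init__(self, mapping: dict[int, tuple[str, int]]):
        labels = sorted(mapping)
        if labels and labels != list(range(labels[0], 1)):
            raise SelectionError(
                f"position labels must run contiguously up to 0, got {labels}"
            )
        self._mapping = dict(mapping)

    @classmethod
    def from_topology(cls, topology: Sequence[Atom], chain_id: str) -> "PeptidePositionMap":
        residue_ids: list[int] = []
        for atom in topology:
            if atom.chain_id == chain_id and atom.residue_id not in residue_ids:
                residue_ids.append(atom.residue_id)
        if not residue_ids:
            raise SelectionError(f"no residues found in chain {chain_id!r}")
        mapping = {
            pos - (len(residue_ids) - 1): (chain_id, rid)
            for pos, rid in enumerate(residue_ids)
        }
        return cls(mapping)

    def __getitem__(self, position: int) -> tuple[str, int]:
        try:
            return self._mapping[position]
        except KeyError:
            raise SelectionError(
                f"position {position} not in map (have {sorted(self._mapping)})"
            ) from None

    def __len__(self) -> int:
        return len(self._mapping)

    @property
    def positions(self) -> list[int]:
        return sorted(self._mapping)

    def selection(
        self, positions: Iterable[int], atom_names: Iterable[str] | None = BACKBONE
    ) -> AtomSelection:
        """Build an :class:`AtomSelection` for the given position labels."""
        chains = set()
        residue_ids = []
        for pos in positions:
            chain, rid = self[pos]
            chains.add(chain)
            residue_ids.append(rid)
        return AtomSelection(
            chain_ids=frozenset(chains),
            residue_ids=tuple(residue_ids),
            atom_names=frozenset(atom_names) if atom_names is not None else None,
        )
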