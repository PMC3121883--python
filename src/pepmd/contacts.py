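"""Geometric polar-contact detection: hydrogen bonds and salt bridges.

Criteria (all configurable):

* hydrogen bond — donor–acceptor heavy-atom distance <= ``d_hb`` (3.5 Å) and
  donor–H–acceptor angle >= ``theta_hb`` (120°).  When the topology carries
  no hydrogens (the common case for backbone-only or coarse inputs) the
  angle test is skipped and the record is flagged ``distance_only``.
* salt bridge — minimum distance between any side-chain cationic N and
  anionic O of opposing charged groups <= ``d_sb`` (4.0 Å).

Phosphoserine (residue names SEP or PSE) is a first-class anionic residue:
its phosphate oxygens carry the charge.  The C-terminal carboxylate (O/OXT
of a chain's last residue) is likewise anionic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trajectory
from .errors import DataError

__all__ = ["ContactParams", "ContactRecord", "ContactReport", "detect_contacts"]

logger = logging.getLogger(__name__)

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HIP",
    "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL", "SEP", "PSE",
}

# side-chain H-bond donors (heavy atom) per residue; backbone N is a donor
# for every residue except proline
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "HIP": {"ND1", "NE2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
    "CYS": {"SG"},
}

# side-chain H-bond acceptors (heavy atom); backbone O/OXT accepts everywhere
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "SEP": {"O1P", "O2P", "O3P", "OG"},
    "PSE": {"O1P", "O2P", "O3P", "OG"},
}

_CATIONS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIP": {"ND1", "NE2"},
}

_ANIONS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "SEP": {"O1P", "O2P", "O3P"},
    "PSE": {"O1P", "O2P", "O3P"},
}


@dataclass(frozen=True)
class ContactParams:
    """Geometric cutoffs for contact detection."""

    d_hb: float = 3.5  # Å, donor-acceptor heavy atom distance
    theta_hb: float = 120.0  # degrees, minimum donor-H-acceptor angle
    d_sb: float = 4.0  # Å, cation N to anion O
    include_cterm_carboxylate: bool = True


@dataclass(frozen=True)
class ContactRecord:
    kind: str  # "hbond" | "saltbridge"
    frame: int
    donor: str  # atom label (cation for salt bridges)
    acceptor: str  # atom label (anion for salt bridges)
    distance: float  # Å
    angle: float | None = None  # degrees, hbond with hydrogens only
    distance_only: bool = False


@dataclass
class ContactReport:
    records: list[ContactRecord] = field(default_factory=list)
    n_frames: int = 0
    hydrogens_present: bool = False

    def occupancy(self) -> pd.DataFrame:
        """Fraction of frames in which each (kind, donor, acceptor) pair occurs."""
        if not self.records:
            return pd.DataFrame(columns=["kind", "donor", "acceptor", "occupancy"])
        df = pd.DataFrame(
            [(r.kind, r.donor, r.acceptor, r.frame) for r in self.records],
            columns=["kind", "donor", "acceptor", "frame"],
        )
        occ = (
            df.drop_duplicates()
            .groupby(["kind", "donor", "acceptor"])
            .size()
            .rename("occupancy")
            .reset_index()
        )
        occ["occupancy"] = occ["occupancy"] / self.n_frames
        return occ.sort_values(["kind", "donor", "acceptor"]).reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.kind, r.frame, r.donor, r.acceptor, r.distance, r.angle, r.distance_only)
                for r in self.records
            ],
            columns=["kind", "frame", "donor", "acceptor", "distance", "angle", "distance_only"],
        )


def _group_labels(topology) -> tuple[dict, dict, list[int], list[int], dict]:
    """Classify topology atoms into donor/acceptor/cation/anion index sets."""
    donors: list[int] = []
    acceptors: list[int] = []
    cation_groups: dict[tuple[str, int], list[int]] = {}
    anion_groups: dict[tuple[str, int], list[int]] = {}
    hydrogens: dict[int, list[int]] = {}

    last_residue: dict[str, int] = {}
    for atom in topology:
        last_residue[atom.chain_id] = max(
            last_residue.get(atom.chain_id, atom.residue_id), atom.residue_id
        )

    warned: set[str] = set()
    for i, atom in enumerate(topology):
        res = atom.residue_name.upper()
        if res not in _STANDARD_RESIDUES:
            if res not in warned:
                logger.warning("unknown residue %r: skipped in charged-group tables", res)
                warned.add(res)
            continue
        name = atom.name
        if name == "N" and res != "PRO":
            donors.append(i)
        if name in _SIDECHAIN_DONORS.get(res, ()):
            donors.append(i)
        if name in ("O", "OXT"):
            acceptors.append(i)
        if name in _SIDECHAIN_ACCEPTORS.get(res, ()):
            acceptors.append(i)
        rkey = (atom.chain_id, atom.residue_id)
        if name in _CATIONS.get(res, ()):
            cation_groups.setdefault(rkey, []).append(i)
        if name in _ANIONS.get(res, ()):
            anion_groups.setdefault(rkey, []).append(i)
        if name in ("O", "OXT") and atom.residue_id == last_residue[atom.chain_id]:
            anion_groups.setdefault(rkey, []).append(i)
        if atom.element == "H" or name.startswith("H"):
            hydrogens.setdefault(atom.residue_id, []).append(i)
    return cation_groups, anion_groups, donors, acceptors, hydrogens


def detect_contacts(traj: Trajectory, params: ContactParams | None = None) -> ContactReport:
    """Detect hydrogen bonds and salt bridges in every frame.

    Contacts within one residue are ignored.  Returns a
    :class:`ContactReport` whose ``occupancy()`` gives per-pair fractions of
    frames with the contact present.
    """
    if params is None:
        params = ContactParams()
    if traj.n_frames == 0:
        raise DataError("empty trajectory")
    topology = traj.topology
    cation_groups, anion_groups, donors, acceptors, hydrogens = _group_labels(topology)
    if not params.include_cterm_carboxylate:
        for rkey in list(anion_groups):
            anion_groups[rkey] = [
                i for i in anion_groups[rkey] if topology[i].name not in ("O", "OXT")
            ]
            if not anion_groups[rkey]:
                del anion_groups[rkey]

    any_h = any(hydrogens.values())
    report = ContactReport(n_frames=traj.n_frames, hydrogens_present=any_h)

    don_idx = np.asarray(donors, dtype=np.intp)
    acc_idx = np.asarray(acceptors, dtype=np.intp)

    for f in range(traj.n_frames):
        coords = traj.coords[f]
        # hydrogen bonds
        if don_idx.size and acc_idx.size:
            diff = coords[don_idx][:, None, :] - coords[acc_idx][None, :, :]
            dist = np.sqrt(np.sum(diff**2, axis=2))
            for di, ai in zip(*np.nonzero(dist <= params.d_hb)):
                d_atom = topology[don_idx[di]]
                a_atom = topology[acc_idx[ai]]
                if (d_atom.chain_id, d_atom.residue_id) == (a_atom.chain_id, a_atom.residue_id):
                    continue
                angle = None
                ok = True
                if any_h:
                    angle = _best_hbond_angle(
                        coords, don_idx[di], acc_idx[ai], hydrogens.get(d_atom.residue_id, [])
                    )
                    ok = angle is not None and angle >= params.theta_hb
                if ok:
                    report.records.append(
                        ContactRecord(
                            kind="hbond",
                            frame=f,
                            donor=d_atom.label(),
                            acceptor=a_atom.label(),
                            distance=float(dist[di, ai]),
                            angle=angle,
                            distance_only=not any_h,
                        )
                    )
        # salt bridges: group-to-group minimum distance
        for ckey, cidx in cation_groups.items():
            for akey, aidx in anion_groups.items():
                if ckey == akey:
                    continue
                d = np.sqrt(
                    np.sum(
                        (coords[np.asarray(cidx)][:, None, :] - coords[np.asarray(aidx)][None, :, :])
                        ** 2,
                        axis=2,
                    )
                )
                dmin = float(d.min())
                if dmin <= params.d_sb:
                    ci, ai = np.unravel_index(int(np.argmin(d)), d.shape)
                    report.records.append(
                        ContactRecord(
                            kind="saltbridge",
                            frame=f,
                            donor=topology[cidx[ci]].label(),
                            acceptor=topology[aidx[ai]].label(),
                            distance=dmin,
                        )
                    )
    return report


def _best_hbond_angle(coords, donor_i, acceptor_i, h_candidates) -> float | None:
    """Largest donor-H-acceptor angle over hydrogens bonded to the donor."""
    best = None
    d = coords[donor_i]
    a = coords[acceptor_i]
    for hi in h_candidates:
        h = coords[hi]
        if np.linalg.norm(h - d) > 1.3:  # not covalently bound to this donor
            continue
        v1 = d - h
        v2 = a - h
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < 1e-12:
            continue
        ang = float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))))
        if best is None or ang > best:
            best = ang
    return best
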