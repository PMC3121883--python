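"""Superposition, RMSD/RMSF and the inter-domain orientation dihedral.

The superposition is the classic Kabsch least-squares fit: the proper
rotation and translation minimizing the RMSD over a fit selection.
Reflections are never returned.  RMSD supports the two-selection scheme used
for peptide ensembles: fit on an anchored sub-selection (e.g. the C-terminal
three residues' backbone), evaluate the deviation over the whole peptide
backbone without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Trajectory
from .errors import DataError, GeometryError, StructureError
from .selections import AtomSelection

__all__ = [
    "SuperpositionResult",
    "kabsch_fit",
    "rmsd",
    "RmsfResult",
    "rmsf",
    "dihedral",
    "interdomain_dihedral",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform ``y = R x + t`` mapping mobile onto reference."""

    rotation: np.ndarray  # (3, 3), proper: det = +1
    translation: np.ndarray  # (3,), Å
    fit_rmsd: float  # Å over the fit selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @property
    def inverse(self) -> "SuperpositionResult":
        rot_inv = self.rotation.T
        return SuperpositionResult(rot_inv, -rot_inv @ self.translation, self.fit_rmsd)


def _check_fit_points(points: np.ndarray, what: str) -> None:
    if points.shape[0] < 3:
        raise GeometryError(f"{what}: need at least 3 fit atoms, got {points.shape[0]}")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise GeometryError(f"{what}: fit atoms are collinear")


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    cm_mob = mobile.mean(axis=0)
    cm_ref = reference.mean(axis=0)
    p = mobile - cm_mob
    q = reference - cm_ref
    a = p.T @ q  # a[k, l] = sum_atoms p_k q_l
    u, _, vt = np.linalg.svd(a)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cm_ref - rot @ cm_mob
    fitted = p @ rot.T
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, fit_rmsd)


def kabsch_fit(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    fit_sel: AtomSelection | None = None,
) -> SuperpositionResult:
    """Least-RMSD superposition of ``mobile`` onto ``reference``.

    With a ``fit_sel``, only the selected atoms define the transform; the
    transform itself applies to all coordinates.  Raises
    :class:`GeometryError` for fewer than three or collinear fit atoms.
    """
    if isinstance(mobile, Frame) and isinstance(reference, Frame):
        if fit_sel is not None:
            idx_m = fit_sel.resolve(mobile.topology)
            idx_r = fit_sel.resolve(reference.topology)
            if len(idx_m) != len(idx_r):
                raise StructureError(
                    "fit selection resolves to different atom counts in the two frames"
                )
        else:
            if mobile.n_atoms != reference.n_atoms:
                raise StructureError("frames have different atom counts")
            idx_m = idx_r = np.arange(mobile.n_atoms)
        mob = mobile.coords[idx_m]
        ref = reference.coords[idx_r]
    else:
        mob = np.asarray(mobile, dtype=float)
        ref = np.asarray(reference, dtype=float)
        if mob.shape != ref.shape:
            raise StructureError("coordinate sets have different shapes")
    _check_fit_points(mob, "mobile")
    _check_fit_points(ref, "reference")
    return _kabsch(mob, ref)


def rmsd(
    a: Frame,
    b: Frame,
    sel: AtomSelection | None = None,
    prefit: SuperpositionResult | None = None,
) -> float:
    """Root-mean-square deviation of ``a`` from ``b`` over ``sel`` (Å).

    If ``prefit`` is given it is applied to ``a`` first and no refit is
    performed — this realizes the two-selection scheme (fit on one selection,
    evaluate on another).  Without ``prefit`` the coordinates are compared
    as-is (no fitting).
    """
    if sel is not None:
        idx_a = sel.resolve(a.topology)
        idx_b = sel.resolve(b.topology)
        if len(idx_a) != len(idx_b):
            raise StructureError("selection resolves to different atom counts")
    else:
        if a.n_atoms != b.n_atoms:
            raise StructureError("frames have different atom counts")
        idx_a = idx_b = np.arange(a.n_atoms)
    xa = a.coords[idx_a]
    if prefit is not None:
        xa = prefit.apply(xa)
    xb = b.coords[idx_b]
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


@dataclass(frozen=True)
class RmsfResult:
    """Per-atom root-mean-square fluctuation about the mean structure."""

    indices: np.ndarray  # topology indices of the measured atoms
    per_atom: np.ndarray  # Å, aligned with `indices`
    topology: tuple

    def ca_by_residue(self) -> dict[tuple[str, int], float]:
        """RMSF of the Cα atom per (chain, residue id)."""
        out: dict[tuple[str, int], float] = {}
        for idx, value in zip(self.indices, self.per_atom):
            atom = self.topology[idx]
            if atom.name == "CA":
                out[(atom.chain_id, atom.residue_id)] = float(value)
        return out


def rmsf(
    traj: Trajectory,
    fit_sel: AtomSelection | None,
    measure_sel: AtomSelection | None = None,
) -> RmsfResult:
    """RMSF over ``measure_sel`` after superposing every frame on the mean.

    With ``fit_sel`` given, frames are first fit to the raw coordinate mean
    over the fit selection, the time-averaged structure is recomputed from
    the fitted frames, and the original frames are refit onto that average
    (one fit-average-refit iteration, the standard stable procedure).
    Starting from the raw mean rather than an arbitrary frame makes the
    result an exact function of the set of frames, independent of their
    order.  ``fit_sel=None`` disables fitting entirely (appropriate when the
    trajectory is already aligned).
    """
    if traj.n_frames < 2:
        raise DataError("RMSF requires at least two frames")
    coords = traj.coords
    if fit_sel is not None:
        fit_idx = fit_sel.resolve(traj.topology)
        try:
            aligned = _align_all(coords, coords.mean(axis=0), fit_idx)
        except GeometryError:
            # degenerate raw mean (e.g. symmetric cancellation): seed from
            # the first frame instead
            aligned = _align_all(coords, coords[0], fit_idx)
        mean_structure = aligned.mean(axis=0)
        aligned = _align_all(coords, mean_structure, fit_idx)
    else:
        aligned = coords
    if measure_sel is not None:
        m_idx = measure_sel.resolve(traj.topology)
    else:
        m_idx = np.arange(traj.n_atoms)
    sub = aligned[:, m_idx, :]
    mean = sub.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    return RmsfResult(indices=m_idx, per_atom=fluct, topology=traj.topology)


def _align_all(coords: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    ref_fit = reference[fit_idx]
    for i in range(coords.shape[0]):
        sup = _kabsch(coords[i][fit_idx], ref_fit)
        out[i] = sup.apply(coords[i])
    return out


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle over four points, IUPAC convention, in (-180, 180].

    cis (eclipsed) = 0°; sign is right-handed looking from p2 toward p3.
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n2 = np.linalg.norm(b2)
    if n2 < 1e-12 or np.linalg.norm(b1) < 1e-12 or np.linalg.norm(b3) < 1e-12:
        raise GeometryError("zero-length bond vector in dihedral")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    if np.linalg.norm(c1) < 1e-12 or np.linalg.norm(c2) < 1e-12:
        raise GeometryError("collinear points in dihedral")
    x = np.dot(c1, c2)
    y = np.dot(np.cross(c1, c2), b2 / n2)
    # IUPAC: angle from (b1,b2) half-plane to (b2,b3) half-plane; the cis
    # geometry (p1 and p4 on the same side) gives x > 0, y = 0 -> 0 deg.
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def _atom_index(topology, atom_id) -> int:
    if isinstance(atom_id, (int, np.integer)):
        if not 0 <= atom_id < len(topology):
            raise StructureError(f"atom index {atom_id} out of range")
        return int(atom_id)
    chain_id, residue_id, name = atom_id
    for i, a in enumerate(topology):
        if a.key == (chain_id, residue_id, name):
            return i
    raise StructureError(f"no atom {atom_id} in topology")


def interdomain_dihedral(
    frame: Frame,
    dom1_sel: AtomSelection,
    dom2_sel: AtomSelection,
    hinge1,
    hinge2,
) -> float:
    """Relative orientation of two domains as a signed dihedral (degrees).

    Computes the mass-weighted centers MC1, MC2 of the two domain selections
    and returns the dihedral over (MC1, hinge1, hinge2, MC2), where the hinge
    atoms are given by topology index or ``(chain_id, residue_id, name)``.
    This is the classic descriptor for inter-domain twist in domain-swapped
    dimers (center of mass — hinge Cα — hinge Cα' — center of mass).
    """
    masses = frame.masses()
    idx1 = dom1_sel.resolve(frame.topology)
    idx2 = dom2_sel.resolve(frame.topology)
    mc1 = np.average(frame.coords[idx1], axis=0, weights=masses[idx1])
    mc2 = np.average(frame.coords[idx2], axis=0, weights=masses[idx2])
    h1 = frame.coords[_atom_index(frame.topology, hinge1)]
    h2 = frame.coords[_atom_index(frame.topology, hinge2)]
    return dihedral(mc1, h1, h2, mc2)
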