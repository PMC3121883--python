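"""Ensemble clustering of bound-peptide conformations.

The pipeline is: pool peptide conformations from several trajectories and
binding sites (with a frame stride), build the all-pairs RMSD matrix under
the two-selection scheme (least-RMSD fit on the anchored C-terminal backbone,
deviation over the whole peptide backbone), cluster with the greedy
GROMOS/Daura maximum-neighbor rule at a fixed cutoff, and summarize cluster
populations and inter-cluster transition statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pairwise import pairwise_two_selection_rmsd
from .core import Atom, Trajectory
from .errors import ConfigError, ContractError, DataError, StructureError
from .selections import AtomSelection

__all__ = [
    "ConformationSet",
    "RmsdMatrix",
    "ClusterResult",
    "TransitionStats",
    "pool_and_subsample",
    "build_rmsd_matrix",
    "gromos_cluster",
    "transition_stats",
]


@dataclass
class ConformationSet:
    """Pooled peptide conformations with full provenance.

    ``coords`` has shape (n_conformations, n_template_atoms, 3); the template
    topology is the peptide-only atom list shared by all pooled sites.
    ``provenance`` carries one row per conformation: trajectory index, site
    index, source frame index and time.
    """

    coords: np.ndarray
    template: tuple[Atom, ...]
    provenance: pd.DataFrame

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _site_template(topology, idx) -> tuple:
    """Comparable template: residue names, atom names, relative residue rank."""
    residues: list[tuple[str, int]] = []
    for i in idx:
        key = (topology[i].chain_id, topology[i].residue_id)
        if key not in residues:
            residues.append(key)
    rank = {key: r for r, key in enumerate(residues)}
    return tuple(
        (topology[i].residue_name, topology[i].name,
         rank[(topology[i].chain_id, topology[i].residue_id)])
        for i in idx
    )


def pool_and_subsample(
    trajs: list[Trajectory],
    site_selections: list[list[AtomSelection]],
    stride: int = 1,
) -> ConformationSet:
    """Pool peptide conformations from all trajectories and binding sites.

    For every trajectory and every site selection, extracts the selected
    atoms from frames 0, stride, 2*stride, ...  All sites must resolve to an
    identical atom-name/residue template so the pooled conformations are
    mutually comparable.  Provenance (trajectory, site, frame, time) is
    retained for transition statistics.
    """
    if stride < 1:
        raise ConfigError(f"stride must be >= 1, got {stride}")
    if len(trajs) != len(site_selections):
        raise ContractError("one site-selection list per trajectory required")
    blocks = []
    rows = []
    template = None
    template_atoms: tuple[Atom, ...] | None = None
    for t_idx, (traj, sels) in enumerate(zip(trajs, site_selections)):
        if not sels:
            raise ContractError(f"trajectory {t_idx} has no site selections")
        for s_idx, sel in enumerate(sels):
            idx = sel.resolve(traj.topology)
            tmpl = _site_template(traj.topology, idx)
            if template is None:
                template = tmpl
                template_atoms = tuple(traj.topology[i] for i in idx)
            elif tmpl != template:
                raise StructureError(
                    f"site {s_idx} of trajectory {t_idx} does not match the "
                    "pooled atom-name/residue template"
                )
            frame_ids = np.arange(0, traj.n_frames, stride)
            blocks.append(traj.coords[frame_ids][:, idx, :])
            for f in frame_ids:
                rows.append((t_idx, s_idx, int(f), float(traj.times[f])))
    coords = np.concatenate(blocks, axis=0)
    provenance = pd.DataFrame(rows, columns=["traj", "site", "frame", "time"])
    assert template_atoms is not None
    return ConformationSet(coords=coords, template=template_atoms, provenance=provenance)


@dataclass
class RmsdMatrix:
    """Symmetric all-pairs dissimilarity matrix (Å) with provenance."""

    values: np.ndarray
    fit_sel: AtomSelection
    rmsd_sel: AtomSelection
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.dtype.kind != "f":
            v = v.astype(float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContractError("RMSD matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        if np.max(np.abs(np.diagonal(self.values))) > 1e-9:
            raise DataError("non-zero diagonal in RMSD matrix")
        if self.n <= 4000:
            if np.any(self.values < 0):
                raise DataError("negative RMSD entry")
            if np.max(np.abs(self.values - self.values.T)) > 1e-9:
                raise DataError("RMSD matrix asymmetric beyond 1e-9 Å")
        else:
            # full checks would need another O(n^2) allocation; spot-check
            rng = np.random.default_rng(0)
            i = rng.integers(0, self.n, 2000)
            j = rng.integers(0, self.n, 2000)
            if np.any(self.values[i, j] < 0):
                raise DataError("negative RMSD entry")
            if np.max(np.abs(self.values[i, j] - self.values[j, i])) > 1e-9:
                raise DataError("RMSD matrix asymmetric beyond 1e-9 Å")


def build_rmsd_matrix(
    conformations: ConformationSet,
    fit_sel: AtomSelection,
    rmsd_sel: AtomSelection,
) -> RmsdMatrix:
    """All-pairs two-selection RMSD matrix.

    Entry (i, j) is the RMSD over ``rmsd_sel`` after the least-RMSD fit of
    conformation j onto i over ``fit_sel``.  The fit/evaluate split
    implements the anchored-fit scheme: superpose on the C-terminal anchor,
    measure deviation over the whole peptide backbone.  The value is
    symmetric in (i, j) — the reverse fit is the inverse rigid transform and
    preserves all deviations — so each pair is computed once.
    """
    fit_idx = fit_sel.resolve(conformations.template)
    eval_idx = rmsd_sel.resolve(conformations.template)
    if len(fit_idx) < 3:
        raise DataError("fit selection must contain at least 3 atoms")
    # float32 storage above ~6000 conformations: the full matrix dominates
    # memory (n^2 entries) while cutoff comparisons need nowhere near 1e-7
    dtype = np.float64 if conformations.n <= 6000 else np.float32
    values = pairwise_two_selection_rmsd(
        conformations.coords[:, fit_idx, :], conformations.coords[:, eval_idx, :],
        dtype=dtype,
    )
    matrix = RmsdMatrix(
        values=values,
        fit_sel=fit_sel,
        rmsd_sel=rmsd_sel,
        provenance=conformations.provenance,
    )
    matrix.validate()
    return matrix


@dataclass
class ClusterResult:
    """Greedy maximum-neighbor clustering of one RMSD matrix.

    Labels are 1-based and ordered by decreasing cluster size; ``centers``
    holds the representative (maximum-neighbor) conformation of each cluster.
    """

    labels: np.ndarray  # (n,), 1-based
    centers: np.ndarray  # (n_clusters,), conformation indices
    sizes: np.ndarray  # (n_clusters,)
    percentages: np.ndarray  # (n_clusters,), sums to 100
    cutoff: float  # Å

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def gromos_cluster(matrix: RmsdMatrix | np.ndarray, cutoff: float) -> ClusterResult:
    """GROMOS (Daura) clustering: greedy maximum-neighbor cluster removal.

    Repeatedly, the unassigned conformation with the most unassigned
    neighbors within ``cutoff`` becomes a cluster center; it and its
    neighbors form the cluster and are removed.  Ties in neighbor count are
    broken toward the lowest conformation index, making the partition
    deterministic.  Singletons are allowed.  Every member is within
    ``cutoff`` of its cluster center by construction (asserted).
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    values = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix)
    n = values.shape[0]
    adj = values <= cutoff
    np.fill_diagonal(adj, False)

    labels = np.zeros(n, dtype=np.intp)
    unassigned = np.ones(n, dtype=bool)
    centers: list[int] = []
    sizes: list[int] = []
    cluster_id = 0
    while unassigned.any():
        un_idx = np.nonzero(unassigned)[0]
        counts = adj[np.ix_(un_idx, un_idx)].sum(axis=1)
        center = int(un_idx[int(np.argmax(counts))])  # argmax -> lowest index on ties
        members = un_idx[adj[center, un_idx]]
        cluster_id += 1
        labels[center] = cluster_id
        labels[members] = cluster_id
        unassigned[center] = False
        unassigned[members] = False
        centers.append(center)
        sizes.append(1 + members.size)

    # renumber by decreasing size; equal sizes keep formation order
    order = sorted(range(cluster_id), key=lambda c: (-sizes[c], c))
    remap = np.empty(cluster_id + 1, dtype=np.intp)
    for new, old in enumerate(order, start=1):
        remap[old + 1] = new
    labels = remap[labels]
    centers_arr = np.array([centers[c] for c in order], dtype=np.intp)
    sizes_arr = np.array([sizes[c] for c in order], dtype=np.intp)
    percentages = 100.0 * sizes_arr / n

    # membership-radius invariant: every member within cutoff of its center
    for k, center in enumerate(centers_arr, start=1):
        members = np.nonzero(labels == k)[0]
        if members.size and float(values[center, members].max()) > cutoff + 1e-12:
            raise ContractError("cluster member beyond cutoff of its center")

    return ClusterResult(
        labels=labels,
        centers=centers_arr,
        sizes=sizes_arr,
        percentages=percentages,
        cutoff=float(cutoff),
    )


@dataclass
class TransitionStats:
    n_transitions: int
    total_time_ps: float
    rate_per_ps: float
    pair_counts: pd.DataFrame  # columns: from, to, count
    per_step_probability: float = 0.0


def transition_stats(
    labels: np.ndarray,
    provenance: pd.DataFrame,
    dt_effective: float,
) -> TransitionStats:
    """Cluster-to-cluster transition statistics along each source series.

    A transition is ``label(t+1) != label(t)`` between consecutive pooled
    frames of the *same* trajectory and site; pooling boundaries never
    contribute.  The rate is transitions per ps of elapsed (strided) time.
    """
    labels = np.asarray(labels)
    if provenance is None or not {"traj", "site", "frame"}.issubset(provenance.columns):
        raise ContractError("provenance with traj/site/frame columns required")
    if len(labels) != len(provenance):
        raise ContractError("one provenance row per label required")
    if dt_effective <= 0:
        raise ConfigError("dt_effective must be positive")

    n_trans = 0
    total_steps = 0
    pairs: dict[tuple[int, int], int] = {}
    df = provenance.reset_index(drop=True)
    for (_, _), group in df.groupby(["traj", "site"], sort=True):
        order = group.sort_values("frame").index.to_numpy()
        seq = labels[order]
        total_steps += max(len(seq) - 1, 0)
        changed = np.nonzero(seq[1:] != seq[:-1])[0]
        n_trans += changed.size
        for i in changed:
            key = (int(seq[i]), int(seq[i + 1]))
            pairs[key] = pairs.get(key, 0) + 1

    total_time = total_steps * dt_effective
    rate = n_trans / total_time if total_time > 0 else 0.0
    pair_df = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(pairs.items())],
        columns=["from", "to", "count"],
    )
    return TransitionStats(
        n_transitions=int(n_trans),
        total_time_ps=float(total_time),
        rate_per_ps=float(rate),
        pair_counts=pair_df,
        per_step_probability=(n_trans / total_steps if total_steps else 0.0),
    )
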