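"""Composed analysis tracks with config, provenance and reproducible seeds.

Two tracks mirror the two halves of a binding-ensemble study:

* ensemble — trajectory(ies) → pooled peptide conformations → RMSD matrix →
  GROMOS clustering → transition statistics, plus per-site RMSF and polar
  contacts.
* energetics — per-window ΔU series → per-window ΔG and σ → leg totals →
  thermodynamic-cycle ΔΔG, optionally compared against a Kd-derived value.

Every output set is written next to a serialized copy of the configuration
and stamped with its hash, so results are fully attributable.  Summary files
contain no timestamps: rerunning with the same config and seed reproduces
them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .clustering import build_rmsd_matrix, gromos_cluster, pool_and_subsample, transition_stats
from .contacts import ContactParams, detect_contacts
from .core import Trajectory
from .errors import ConfigError, DataError
from .fep import CycleSpec, accumulate, cycle_ddg, ddg_from_kd, read_window_dir
from .io import read_structure, write_structure
from .metrics import rmsf
from .selections import AtomSelection, PeptidePositionMap

__all__ = ["RunConfig", "run_ensemble_track", "run_energetics_track", "config_hash"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every field except input paths has
    a documented default."""

    track: str = "ensemble"  # ensemble | energetics
    trajectories: list[str] = field(default_factory=list)  # input PDB paths
    peptide_chains: list[str] = field(default_factory=lambda: ["P"])  # one site per chain
    stride: int = 4  # frame-picking stride for pooling
    cutoff: float = 1.5  # Å, clustering cutoff
    fit_positions: list[int] | None = None  # C-terminal positions for the
    # anchored fit (e.g. [0, -1, -2]); None fits on the whole peptide backbone
    backbone_atoms: list[str] = field(default_factory=lambda: ["N", "CA", "C"])
    dt: float = 1.0  # ps between stored frames when reading PDB
    contacts: bool = True
    temperature: float = 300.0  # K
    seed: int = 2011  # fixed documented default, never wall clock
    bound_windows: str | None = None  # window dir, energetics track
    free_windows: str | None = None
    kd_wt: float | None = None  # molar
    kd_mut: float | None = None
    out_prefix: str = "pepmd_run"
    matrix_csv_max: int = 2000  # matrix CSV emitted only up to this n

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def config_hash(cfg: RunConfig) -> str:
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _emit_config(cfg: RunConfig, prefix: Path) -> str:
    digest = config_hash(cfg)
    _write_json({"config": cfg.to_dict(), "config_hash": digest, "version": _version},
                prefix.parent / f"{prefix.name}_config.json")
    return digest


def run_ensemble_track(
    cfg: RunConfig, trajectories: list[Trajectory] | None = None
) -> dict[str, Any]:
    """Trajectory → pooling → RMSD matrix → clustering → transitions (+RMSF,
    contacts).  Returns the summary dict; artifacts land at ``out_prefix``."""
    t0 = time.perf_counter()
    prefix = Path(cfg.out_prefix)
    digest = _emit_config(cfg, prefix)

    if trajectories is None:
        if not cfg.trajectories:
            raise ConfigError("ensemble track requires at least one trajectory path")
        trajectories = [read_structure(p, dt=cfg.dt) for p in cfg.trajectories]
    logger.info("ensemble track: %d trajectories, stride %d", len(trajectories), cfg.stride)

    backbone = frozenset(cfg.backbone_atoms)
    site_sels = [
        [AtomSelection(chain_ids=frozenset({chain})) for chain in cfg.peptide_chains]
        for _ in trajectories
    ]
    conformations = pool_and_subsample(trajectories, site_sels, cfg.stride)

    rmsd_sel = AtomSelection(atom_names=backbone)
    if cfg.fit_positions is not None:
        pmap = PeptidePositionMap.from_topology(
            conformations.template, conformations.template[0].chain_id
        )
        fit_sel = pmap.selection(cfg.fit_positions, atom_names=backbone)
    else:
        fit_sel = rmsd_sel

    matrix = build_rmsd_matrix(conformations, fit_sel, rmsd_sel)
    clusters = gromos_cluster(matrix, cfg.cutoff)
    dt_effective = cfg.stride * trajectories[0].dt
    transitions = transition_stats(clusters.labels, conformations.provenance, dt_effective)

    labels_df = conformations.provenance.copy()
    labels_df["cluster"] = clusters.labels
    labels_df.to_csv(prefix.parent / f"{prefix.name}_labels.csv", index=False)
    if matrix.n <= cfg.matrix_csv_max:
        np.savetxt(prefix.parent / f"{prefix.name}_matrix.csv", matrix.values,
                   delimiter=",", fmt="%.6f")

    reps = Trajectory(
        conformations.template,
        conformations.coords[clusters.centers],
        dt=max(dt_effective, 1e-6),
    )
    write_structure(reps, prefix.parent / f"{prefix.name}_representatives.pdb")

    summary: dict[str, Any] = {
        "config_hash": digest,
        "version": _version,
        "track": "ensemble",
        "n_conformations": int(conformations.n),
        "n_clusters": int(clusters.n_clusters),
        "cluster_sizes": clusters.sizes.tolist(),
        "cluster_percentages": [round(float(p), 1) for p in clusters.percentages],
        "cluster_centers": [
            {
                "conformation": int(c),
                **{k: int(v) if k != "time" else float(v)
                   for k, v in conformations.provenance.iloc[int(c)].items()},
            }
            for c in clusters.centers
        ],
        "cutoff_angstrom": cfg.cutoff,
        "transitions": {
            "count": transitions.n_transitions,
            "total_time_ps": transitions.total_time_ps,
            "rate_per_ps": transitions.rate_per_ps,
            "per_step_probability": transitions.per_step_probability,
        },
    }

    rmsf_rows = []
    rmsf_errors = {}
    for t_idx, traj in enumerate(trajectories):
        for chain in cfg.peptide_chains:
            sel_fit = AtomSelection(chain_ids=frozenset({chain}), atom_names=backbone)
            sel_ca = AtomSelection(chain_ids=frozenset({chain}), atom_names=frozenset({"CA"}))
            try:
                result = rmsf(traj, sel_fit, sel_ca)
            except DataError as exc:
                rmsf_errors[f"traj{t_idx}/chain {chain}"] = str(exc)
                continue
            for (chain_id, rid), value in result.ca_by_residue().items():
                rmsf_rows.append((t_idx, chain_id, rid, value))
    if rmsf_rows:
        rmsf_df = pd.DataFrame(rmsf_rows, columns=["traj", "chain", "residue_id", "rmsf"])
        rmsf_df.to_csv(prefix.parent / f"{prefix.name}_rmsf.csv", index=False)
        summary["rmsf"] = {
            "mean_ca_rmsf": float(rmsf_df["rmsf"].mean()),
            "max_ca_rmsf": float(rmsf_df["rmsf"].max()),
        }
    if rmsf_errors:
        summary.setdefault("rmsf", {})
        summary["rmsf"]["errors"] = rmsf_errors

    if cfg.contacts:
        report = detect_contacts(trajectories[0], ContactParams())
        occ = report.occupancy()
        occ.to_csv(prefix.parent / f"{prefix.name}_contacts.csv", index=False)
        summary["contacts"] = {
            "n_records": len(report.records),
            "n_pairs": int(len(occ)),
            "hydrogens_present": report.hydrogens_present,
        }

    _write_json(summary, prefix.parent / f"{prefix.name}_summary.json")
    logger.info("ensemble track done in %.1f s", time.perf_counter() - t0)
    return summary


def run_energetics_track(cfg: RunConfig) -> dict[str, Any]:
    """Window series → per-leg ΔG totals → cycle ΔΔG (+ optional Kd block)."""
    t0 = time.perf_counter()
    prefix = Path(cfg.out_prefix)
    digest = _emit_config(cfg, prefix)

    legs: dict[str, Any] = {}
    results = {}
    for leg_name, directory in (("bound", cfg.bound_windows), ("free", cfg.free_windows)):
        if directory is None:
            continue
        windows = read_window_dir(directory)
        result = accumulate(windows)
        results[leg_name] = result
        legs[leg_name] = {
            "n_windows": result.n_windows,
            "total_dg_kcal_per_mol": result.total_dg,
            "total_sigma_kcal_per_mol": result.total_sigma,
            "flags": result.flags,
            "window_dg": result.window_dg.tolist(),
            "window_sigma": result.window_sigma.tolist(),
        }
    if not legs:
        raise ConfigError("energetics track requires bound_windows and/or free_windows")

    out: dict[str, Any] = {
        "config_hash": digest,
        "version": _version,
        "track": "energetics",
        "legs": legs,
    }
    if "bound" in results and "free" in results:
        ddg, sigma = cycle_ddg(CycleSpec(bound_leg=results["bound"], free_leg=results["free"]))
        out["cycle"] = {
            "ddg_kcal_per_mol": ddg,
            "sigma_kcal_per_mol": sigma,
        }
    if cfg.kd_wt is not None and cfg.kd_mut is not None:
        out["kd_comparison"] = {
            "kd_wt_molar": cfg.kd_wt,
            "kd_mut_molar": cfg.kd_mut,
            "temperature_K": cfg.temperature,
            "ddg_kcal_per_mol": ddg_from_kd(cfg.kd_wt, cfg.kd_mut, cfg.temperature),
        }

    _write_json(out, prefix.parent / f"{prefix.name}_fep.json")
    logger.info("energetics track done in %.1f s", time.perf_counter() - t0)
    return out
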