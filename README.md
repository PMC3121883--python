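# pepmd

Analysis toolkit for molecular-dynamics ensembles of peptides bound to
protein interaction domains — the post-simulation half of a binding study
such as a PDZ-domain / C-terminal-peptide system: how many distinct bound
conformations does the peptide visit, with what weights and exchange rates,
which polar contacts anchor it, and how much does a chemical modification
(e.g. serine phosphorylation) shift the binding free energy.

It is aimed at simulators who already have trajectories (or want
ground-truth-known synthetic stand-ins) and need the downstream statistics
done carefully: deterministic clustering, honest error bars on
exponential-averaging free energies, and reproducible, config-stamped
outputs.

## What it computes

**Conformational clustering (GROMOS/Daura rule).** Peptide conformations are
pooled from multiple trajectories and binding sites with a frame stride,
pairwise dissimilarities are least-RMSD fits on a *fit* selection evaluated
over a separate *RMSD* selection (e.g. fit on the anchored C-terminal
three-residue backbone, measure over the whole peptide backbone), and the
greedy maximum-neighbor rule partitions the ensemble at a cutoff (1.5 Å by
default): the conformation with the most neighbors within the cutoff becomes
a cluster center, it and its neighbors are removed, repeat. Ties break to
the lowest index, so partitions are deterministic. Cluster percentages,
representative structures and inter-cluster transition rates come out the
other end. The all-pairs kernel (quaternion superposition, no per-pair
LAPACK calls) handles 2×10⁸ pairs on one core in about a minute.

**Structural metrics.** Kabsch superposition (proper rotations only),
two-selection RMSD, RMSF about the mean structure with a fit–average–refit
iteration, the inter-domain orientation dihedral
(center-of-mass – hinge Cα – hinge Cα′ – center-of-mass), and geometric
hydrogen-bond / salt-bridge detection with per-pair occupancies
(phosphoserine and C-terminal carboxylates are first-class charged groups).

**Free-energy perturbation.** Per λ-window the Zwanzig estimator

    ΔG_k = −k_B T · ln ⟨ exp(−ΔU_k / k_B T) ⟩

computed with a log-sum-exp shift so large |ΔU| cannot overflow. The window
error is first-order propagation of the standard error of the exponential
average through the logarithm, with the variance inflated by the sampling
ratio (1 + 2τ), τ being the integrated autocorrelation time of the series —
so correlated samples widen the error bar, as they should. Windows tile
λ ∈ [0, 1] (schedules can be densified toward the endpoints); totals add,
variances add in quadrature; the thermodynamic cycle closes as
ΔΔG_bind = ΔG_alch,bound − ΔG_alch,free; and measured dissociation constants
convert through ΔΔG = R·T·ln(Kd_b/Kd_a) for comparison.

**Synthetic data with known truth.** A Markov-modulated multi-conformer
trajectory generator (exact stationary populations, isotropic positional
noise), an exact-dihedral two-domain fixture, and AR(1) Gaussian ΔU window
series whose free energy is known in closed form
(ΔG_k = μ_k − σ_k²/(2 k_B T)). Every recovery claim in the test suite is
checked against these exact ground truths.

## Worked example

```python
import numpy as np
from pepmd import (
    AtomSelection, BACKBONE, default_four_state_spec,
    generate_multistate_trajectory, pool_and_subsample, build_rmsd_matrix,
    gromos_cluster, transition_stats, FepSyntheticSpec, generate_fep_samples,
    accumulate, ddg_from_kd,
)

# four bound conformations with populations 0.4/0.3/0.2/0.1, 0.3 Å noise
spec = default_four_state_spec(n_frames=5000, seed=42)
traj, _ = generate_multistate_trajectory(spec)

pooled = pool_and_subsample(
    [traj], [[AtomSelection(chain_ids=frozenset({"P"}))]], stride=4)
bb = AtomSelection(atom_names=BACKBONE)
clusters = gromos_cluster(build_rmsd_matrix(pooled, bb, bb), cutoff=1.5)
stats = transition_stats(clusters.labels, pooled.provenance,
                         dt_effective=4 * traj.dt)
print(f"{clusters.n_clusters} clusters from {pooled.n} conformations")
print("percentages:", [float(round(p, 1)) for p in clusters.percentages])
print(f"transition rate: {stats.rate_per_ps:.3f} /ps")

fep_spec = FepSyntheticSpec(mu=[0.6] * 10, sigma=[0.4] * 10, ar1_phi=0.3,
                            n_samples=5000, seed=42)
windows, truth = generate_fep_samples(fep_spec)
leg = accumulate(windows)
print(f"leg ΔG = {leg.total_dg:.3f} ± {leg.total_sigma:.3f} kcal/mol "
      f"(exact {truth:.3f})")
print(f"Kd 7.2 µM → 100 µM at 300 K: "
      f"ΔΔG = {ddg_from_kd(7.2e-6, 1e-4, 300.0):.2f} kcal/mol")
```

prints

```
4 clusters from 1250 conformations
percentages: [39.9, 30.7, 19.2, 10.2]
transition rate: 0.087 /ps
leg ΔG = 4.650 ± 0.027 kcal/mol (exact 4.658)
Kd 7.2 µM → 100 µM at 300 K: ΔΔG = 1.57 kcal/mol
```

The clustering recovers all four seeded conformers with percentages within
sampling error of the stationary populations; the ten-window leg total lands
within one reported σ of the exact Gaussian value; and the Kd ratio
reproduces the analytic 1.57 kcal/mol.

The same analyses are available from the shell via the `pepmd` console
script (`simulate-traj`, `simulate-fep`, `cluster`, `rmsf`, `dihedral`,
`contacts`, `fep-estimate`, `kd2ddg`, and `run` for YAML-configured composed
tracks). Exit codes: 0 ok, 2 configuration error, 3 data error.

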