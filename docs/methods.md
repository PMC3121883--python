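# Methods

This note records the models, estimators and numerical choices behind
`pepmd`, and what the synthetic benchmarks do and do not demonstrate.

## Units and conventions

Coordinates and distances in Å, times in ps, energies in kcal/mol,
temperatures in K. A single molar gas constant
R = 1.987204×10⁻³ kcal/(mol·K) is used everywhere (per-molecule and
per-mole expressions therefore cannot diverge). "Backbone" means the
mainchain heavy atoms {N, CA, C}; the carbonyl O can be included by passing
`BACKBONE_WITH_O`. Dihedral angles follow the IUPAC convention: cis = 0°,
sign right-handed looking along the central bond, range (−180°, 180°].
Peptide residues may be addressed by C-terminal position labels
(0 = last residue, −1, −2, …) through `PeptidePositionMap`.

## Superposition and RMSD

`kabsch_fit` returns the least-squares optimal *proper* rotation plus
translation (SVD construction with determinant correction; reflections are
never returned). Degenerate inputs — fewer than three fit atoms, or
collinear fit atoms, detected by a rank test at tolerance 1e-9 — raise a
geometry error rather than returning an ill-defined rotation.

`rmsd` deliberately performs no fitting of its own. Superposition is a
separate, explicit step, which makes the two-selection scheme first-class:
fit on one selection (e.g. the anchored C-terminal three-residue backbone of
a bound peptide), then evaluate the deviation over another (the whole
peptide backbone) under that same transform. This is the standard protocol
for ensembles where one part of the molecule is a physical anchor.

`rmsf` measures per-atom fluctuation about the time-mean structure. When a
fit selection is given, frames are superposed on the raw coordinate mean,
the mean is recomputed from the fitted frames, and the frames are refit once
(fit–average–refit). Seeding from the raw mean rather than an arbitrary
frame makes the result an exact function of the *set* of frames — RMSF is a
per-atom moment and must not depend on frame order. With fitting disabled
the closed form for isotropic noise applies exactly: RMSF → σ√3.

The choice of RMSF fit reference is scientifically loaded for bound
peptides: fitting on the whole peptide backbone absorbs arm motion into the
reference, while fitting on the C-terminal anchor attributes all arm motion
to the arm. Both are supported; neither is hard-wired.

## Inter-domain orientation

For a domain-swapped dimer the relative domain orientation is summarized by
the signed dihedral over (MC1, hinge Cα, hinge Cα′, MC2), where MC1/MC2 are
mass-weighted centers of the two domain selections and the hinge atoms sit
at the dimer interface. The synthetic two-domain fixture constructs this
geometry so the dihedral equals the requested angle *exactly*, which makes
the metric testable to 1e-6° without any reference implementation.

## Polar contacts

Geometric criteria, all configurable: hydrogen bond = donor–acceptor
heavy-atom distance ≤ 3.5 Å and donor–H–acceptor angle ≥ 120° (when the
topology has no hydrogens the angle test is skipped and records are flagged
`distance_only`); salt bridge = minimum distance ≤ 4.0 Å between side-chain
cationic N (Arg, Lys, His⁺) and anionic O groups (Asp, Glu, phosphoserine
phosphate oxygens, C-terminal carboxylate). These are common literature
defaults, not fitted values. Phosphoserine is recognized under residue names
SEP and PSE. Occupancy is the fraction of frames in which a given
donor/acceptor (or cation/anion) pair is in contact. Intra-residue pairs are
ignored; unknown residues are skipped with a logged warning.

## Ensemble clustering

Conformations are pooled across trajectories and binding sites (all sites
must present an identical residue/atom-name template) with a frame stride,
and full provenance (trajectory, site, frame, time) travels with every
conformation. The dissimilarity matrix applies the two-selection scheme per
pair: fit conformation j onto i over the fit selection, evaluate RMSD over
the measure selection. The value is symmetric in (i, j) — the reverse fit is
the inverse rigid transform — so each pair is computed once and mirrored.

The pair kernel uses the quaternion formulation of the superposition
problem: the optimal rotation is the top eigenvector of the 4×4 key matrix,
found by Newton iteration on its characteristic quartic with the eigenvector
from cofactors. All arithmetic is scalar double precision inside a numba
kernel — no per-pair LAPACK calls — which is what makes 2×10⁸ pairs feasible
on one core (~1 minute). Correctness is cross-checked in the tests against
SVD Kabsch (numpy/scipy) to 1e-9 and against a derivative-free rotation
search. Matrices above 6000 conformations are *stored* float32 (the 20,000²
matrix is 1.6 GB; float64 would double it) while all arithmetic stays
float64; the ~1e-7 relative storage rounding is irrelevant at a 1.5 Å
cutoff.

Clustering is the greedy maximum-neighbor rule: repeatedly take the
unassigned conformation with the most unassigned neighbors within the
cutoff as a center, remove it with its neighbors as a cluster. Ties in
neighbor count break to the lowest conformation index — a total rule, so
partitions are deterministic and reproducible. The representative of a
cluster is its center (the max-neighbor conformation), not a recomputed
medoid. Labels are renumbered by decreasing size (formation order on size
ties). Percentages are reported to 0.1%.

Two provable invariants are asserted on every run or property-tested:
members lie within the cutoff of their center, and labels partition the
set. One intuitive expectation is **false** and documented as such: the
number of clusters is *not* monotone in the cutoff. Enlarging the neighbor
graph can promote a different conformation to first center, and after its
(larger) cluster is removed the remainder can fragment into more clusters.
Counterexamples arise in roughly 1% of small random instances; one is
pinned as a regression test. Consequence for practice: cluster *counts*
from this algorithm should not be compared across cutoffs point by point.

Transition statistics count label changes only between consecutive frames
of the same trajectory and site — pooling boundaries never contribute — and
report transitions per ps of strided time plus per-pair counts.

## Free-energy estimation

Per window, the Zwanzig (exponential averaging) estimator
ΔG_k = −RT·ln⟨e^{−ΔU/RT}⟩ is evaluated through a log-sum-exp with max
shift, so arbitrarily large |ΔU| is safe. Each window may carry an
equilibration prefix to discard (default 0: the synthetic series are
stationary).

The statistical error is first-order (delta-method) propagation: with
m = ⟨e^{−ΔU/RT}⟩ and SE(m)² = var(e^{−ΔU/RT})·(1+2τ)/N,

    σ_k = RT · SE(m) / m,

computed under a common max shift so the ratio is overflow-safe. The
integrated autocorrelation time τ is the sum of normalized autocovariances
up to (excluding) the first lag below 0.05 — a simple positive-sequence
style truncation; the threshold is configurable. For an AR(1) process with
lag-1 coefficient φ the exact sampling ratio is (1+φ)/(1−φ); the truncated
estimator gives 2.875 of the exact 3.0 at φ = 0.5, a ~4% conservative-side
bias that is inside every tolerance used here. A zero-variance series
returns ratio 1 with a degenerate flag; windows with effective sample size
below 10 are flagged.

Windows must tile λ ∈ [0, 1] contiguously (gaps and overlaps are schedule
errors naming the breakpoint). Totals are sums; total variance is the sum
of per-window variances — windows are treated as independent observables.
`lambda_schedule` warps a uniform grid by the symmetric Beta(d, d) CDF:
d = 1 is exactly uniform, d > 1 concentrates breakpoints near the endpoints
(narrower windows where alchemical integrands are steepest). The cycle
closes as ΔΔG_bind = ΔG_alch,bound − ΔG_alch,free with errors in
quadrature, and `ddg_from_kd` provides the experimental comparison value
R·T·ln(Kd_b/Kd_a).

Scope note: dual-topology bookkeeping and counterion co-transformation are
sampling-side concerns of the alchemical MD engine. The estimator consumes
only ΔU series and assumes they describe a well-posed, charge-neutral
transformation.

## Synthetic generators

All generators are deterministic functions of their integer seed.

*Multi-state trajectories.* Frame t is `reference_frames[s_t]` plus i.i.d.
Gaussian displacement of width σ on every coordinate, with s_t a Markov
chain started from its stationary distribution (so occupation statistics
are unbiased at any length). The packaged four-conformer fixture uses
idealized hairpin / L-shape / extended / V-shape Cα traces (3.8 Å spacing,
alternating-plane zigzag backbone so no ≥3-atom selection is collinear)
sharing an identical C-terminal anchor. Backbone-fit inter-state RMSDs are
3.8–11.4 Å; at the default σ = 0.3 Å the within-state distance to a cluster
center stays below ~0.95 Å, so recovery at a 1.5 Å cutoff is unambiguous.
The default transition matrix is the independence chain (every row equals
the stationary vector): labels are i.i.d., occupation counts are exactly
multinomial, and the binomial standard error is the exact yardstick for
percentage recovery. dt defaults to 2 ps per stored frame.

A validity requirement is enforced at construction: pairwise backbone RMSD
between reference frames must exceed 3σ. Note this is necessary, not
sufficient, for recovery under the *anchored* two-selection metric: with
isotropic noise on all atoms, a 9-atom anchor fit is rotationally
ill-conditioned about the anchor's long axis, and the upstream arm acts as
a lever that amplifies fit noise several-fold (measured p99.9 within-state
distances above 2 Å at σ = 0.3). Recovery benchmarks therefore use the
whole-backbone fit — the metric in which the separability requirement is
stated — while the anchored scheme remains the protocol option for real
analyses (where anchor atoms genuinely fluctuate much less than σ of the
arm) and is validated by exactness and invariance tests. This is the main
respect in which the i.i.d.-noise synthetic model is *less* favorable than
real data: real bound peptides have quiet anchors.

*FEP windows.* Stationary AR(1) series with exact Normal(μ_k, σ_k²)
marginals: x_t = μ + φ(x_{t−1} − μ) + ε_t, ε ~ N(0, σ²(1−φ²)), x_0 drawn
from the marginal. The exact window free energy is μ_k − σ_k²/(2RT)
(Gaussian closed form, verified independently by quadrature in the tests),
so total ΔG and cycle ΔΔG ground truths are exact. AR(1) is the minimal
short-memory model; the error theory depends only on the scalar τ, so
nothing would be learned from a richer process.

What the synthetic benchmarks do **not** show: force-field realism,
water/ion effects, conformational sampling adequacy of real MD, hydrogen
placement for H-bond angles, or the behavior of the estimators under
non-Gaussian ΔU tails (where exponential averaging is known to be slow to
converge). Published headline numbers from real trajectory studies
(specific cluster counts, ~kcal-scale cycle ΔΔGs with multi-kcal error
bars) require the original trajectories and are out of scope by design.

## Problem sizes in the shipped checks

The acceptance script and test suite run: 20,000-frame / 20,000-conformation
clustering recovery (the full 2×10⁸-pair matrix, ~1–2 minutes), a
10⁶-sample Gaussian window, two 16-window legs at 4,000 samples per window,
200 replicate windows for coverage, and 10⁵-sample series for the sampling
ratio. These sizes give 3-standard-error assertions enough resolution to
fail loudly on real defects while keeping a full run in a few minutes on
one core.

## Known limitations

* Hydrogen-bond detection without hydrogens is distance-only (flagged); no
  donor-geometry inference is attempted.
* The τ estimator's hard truncation slightly underestimates τ for strongly
  correlated series (conservative direction for effective-n, optimistic for
  σ by the same few percent; ~4% at φ = 0.5).
* Only the Zwanzig estimator is provided — no BAR/MBAR — matching the
  estimator the error model belongs to.
* Multi-model PDB is the only native trajectory format; binary formats
  would enter through a third-party reader behind the same Trajectory
  contract but are not wired in.
* Greedy cluster counts are not comparable across cutoffs (see above).
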