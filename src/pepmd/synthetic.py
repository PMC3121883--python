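"""Ground-truth-known synthetic inputs for every pipeline stage.

Three generators:

* :func:`generate_multistate_trajectory` — a bound peptide that interconverts
  among a small set of distinct conformations.  State labels follow a Markov
  chain with a known stationary distribution; coordinates are the state's
  reference structure plus isotropic Gaussian positional noise.  This
  emulates what ensemble clustering sees in a real binding simulation: a few
  well-separated conformers populated with known weights.
* :func:`generate_two_domain_frame` — a rigid two-domain geometry whose
  inter-domain dihedral (center of mass — hinge — hinge' — center of mass)
  equals a requested angle exactly, by construction.
* :func:`generate_fep_samples` — per-λ-window energy-difference series with
  Gaussian marginals and AR(1) autocorrelation.  For a Gaussian ΔU the
  exponential-average free energy is available in closed form,
  ΔG_k = μ_k − σ_k²/(2 k_B T), so the total free energy is exact ground
  truth for estimator tests.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Atom, Frame, Trajectory
from .errors import ConfigError
from .fep import KB_KCAL_PER_MOL_K, FepWindow, lambda_schedule
from .metrics import kabsch_fit, rmsd
from .selections import BACKBONE, AtomSelection

__all__ = [
    "MultiStateSpec",
    "FepSyntheticSpec",
    "TwoDomainFixture",
    "reference_peptide_frames",
    "default_four_state_spec",
    "generate_multistate_trajectory",
    "generate_two_domain_frame",
    "generate_fep_samples",
]

# 12-residue PDZ-binding peptide sequence (three-letter codes, N- to C-term)
_PEPTIDE_SEQUENCE = (
    "ALA", "SER", "SER", "ARG", "PRO", "ARG", "PRO", "ASP", "ASP", "LEU", "GLU", "ILE",
)

_MASS = {"N": 14.007, "C": 12.011, "O": 15.999}
_CA_STEP = 3.8  # Å between consecutive Cα atoms

# Unit step directions walking N-ward from the anchored C-terminal residue.
# All four shapes share the C-terminal anchor; the upstream arm differs
# grossly, giving inter-state backbone RMSDs of several Å.
_SHAPE_STEPS: dict[str, list[tuple[float, float, float]]] = {
    "extended": [(-1, 0, 0)] * 9,
    "hairpin": [(-1, 0, 0)] * 2 + [(0, 1, 0)] + [(1, 0, 0)] * 6,
    "lshape": [(-1, 0, 0)] * 2 + [(0, 1, 0)] * 7,
    "vshape": [(-1, 0, 0)] * 2 + [(0.7071067811865476, 0, 0.7071067811865476)] * 7,
}


def _peptide_topology(n_residues: int, chain_id: str) -> tuple[Atom, ...]:
    sequence = _PEPTIDE_SEQUENCE[-n_residues:]
    atoms = []
    for i, res in enumerate(sequence):
        rid = i + 1
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                Atom(
                    name=name,
                    residue_name=res,
                    residue_id=rid,
                    chain_id=chain_id,
                    element=name[0],
                    mass=_MASS[name[0]],
                )
            )
    return tuple(atoms)


def _backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """Place N, CA, C, O for each residue from an idealized Cα trace."""
    n_res = ca.shape[0]
    coords = np.empty((n_res * 4, 3))
    for k in range(n_res):
        prev_dir = ca[k - 1] - ca[k] if k > 0 else ca[k] - ca[k + 1]
        next_dir = ca[k + 1] - ca[k] if k < n_res - 1 else ca[k] - ca[k - 1]
        d = next_dir / np.linalg.norm(next_dir)
        p1 = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(p1) < 1e-6:
            p1 = np.cross(d, [0.0, 1.0, 0.0])
        p1 = p1 / np.linalg.norm(p1)
        p2 = np.cross(d, p1)
        # alternate the zigzag plane per residue: a 3-D transverse footprint
        # keeps any >=3-residue fit selection rotationally well-conditioned
        perp = p1 if k % 2 == 0 else p2
        other = p2 if k % 2 == 0 else p1
        n_pos = ca[k] + 0.33 * prev_dir + 0.8 * perp
        c_pos = ca[k] + 0.33 * next_dir - 0.8 * perp
        o_pos = c_pos + 1.23 * other
        coords[4 * k : 4 * k + 4] = [n_pos, ca[k], c_pos, o_pos]
    return coords


def reference_peptide_frames(
    n_residues: int = 12, chain_id: str = "P"
) -> dict[str, Frame]:
    """Idealized bound-peptide conformations sharing one topology.

    Returns frames named ``hairpin``, ``lshape``, ``extended`` and
    ``vshape``, built from an idealized backbone geometry: the three
    C-terminal residues are identical across shapes (the anchored part of a
    bound peptide) while the upstream arm adopts grossly different paths.
    """
    if not 4 <= n_residues <= len(_PEPTIDE_SEQUENCE):
        raise ConfigError(f"n_residues must be in [4, {len(_PEPTIDE_SEQUENCE)}]")
    topology = _peptide_topology(n_residues, chain_id)
    n_steps = n_residues - 3
    frames = {}
    for shape in ("hairpin", "lshape", "extended", "vshape"):
        steps = _SHAPE_STEPS[shape][-n_steps:] if n_steps > 0 else []
        # C-terminal anchor Cαs at x = 0, 3.8, 7.6
        ca = np.zeros((n_residues, 3))
        ca[-1] = (2 * _CA_STEP, 0, 0)
        ca[-2] = (_CA_STEP, 0, 0)
        ca[-3] = (0, 0, 0)
        pos = ca[-3].copy()
        for j, step in enumerate(steps):
            pos = pos + _CA_STEP * np.asarray(step, float)
            ca[-4 - j] = pos
        frames[shape] = Frame(topology, _backbone_from_ca(ca))
    return frames


@dataclass
class MultiStateSpec:
    """Specification of a multi-conformation bound-peptide trajectory.

    ``transition_matrix`` must be row-stochastic with
    ``stationary_populations`` as its stationary vector; reference frames
    must be separated by more than ``3 * noise_sigma`` in backbone RMSD so
    that clustering recovery is well-posed.
    """

    reference_frames: list[Frame]
    stationary_populations: np.ndarray
    transition_matrix: np.ndarray
    noise_sigma: float  # Å
    n_frames: int
    dt: float = 2.0  # ps between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        self.stationary_populations = np.asarray(self.stationary_populations, float)
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.validate()

    def validate(self) -> None:
        n = len(self.reference_frames)
        if n == 0:
            raise ConfigError("at least one reference frame required")
        topo = self.reference_frames[0].topology
        for f in self.reference_frames[1:]:
            if f.topology != topo:
                raise ConfigError("reference frames must share one topology")
        if self.stationary_populations.shape != (n,):
            raise ConfigError("one stationary population per state required")
        if np.any(self.stationary_populations < 0) or abs(
            self.stationary_populations.sum() - 1.0
        ) > 1e-9:
            raise ConfigError("stationary populations must be a probability vector")
        if self.transition_matrix.shape != (n, n):
            raise ConfigError("transition matrix must be n_states x n_states")
        if np.any(self.transition_matrix < 0) or np.any(
            np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ConfigError("transition matrix must be row-stochastic (rows sum to 1)")
        resid = self.stationary_populations @ self.transition_matrix - self.stationary_populations
        if np.max(np.abs(resid)) > 1e-9:
            raise ConfigError("stationary_populations is not stationary for transition_matrix")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be positive")
        if self.noise_sigma > 0:
            sel = AtomSelection(atom_names=BACKBONE)
            for i in range(n):
                for j in range(i + 1, n):
                    fi, fj = self.reference_frames[i], self.reference_frames[j]
                    sup = kabsch_fit(fj, fi, sel)
                    d = rmsd(fj, fi, sel, prefit=sup)
                    if d <= 3.0 * self.noise_sigma:
                        raise ConfigError(
                            f"reference frames {i} and {j} separated by only "
                            f"{d:.2f} Å backbone RMSD (< 3 x noise_sigma)"
                        )

    @property
    def n_states(self) -> int:
        return len(self.reference_frames)


def default_four_state_spec(
    n_frames: int = 20000,
    populations: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1),
    noise_sigma: float = 0.3,
    dt: float = 2.0,
    seed: int = 0,
    n_residues: int = 12,
    chain_id: str = "P",
) -> MultiStateSpec:
    """The canonical four-conformer ensemble used for recovery tests.

    The transition matrix is the independence chain (every row equals the
    stationary vector), so state labels are i.i.d. draws and occupation
    counts are exactly multinomial — the cleanest possible ground truth for
    the percentage-recovery readout.
    """
    frames = reference_peptide_frames(n_residues, chain_id)
    refs = [frames["hairpin"], frames["lshape"], frames["extended"], frames["vshape"]]
    pops = np.asarray(populations, float)
    if pops.shape != (4,):
        raise ConfigError("default spec has exactly four states")
    matrix = np.tile(pops, (4, 1))
    return MultiStateSpec(
        reference_frames=refs,
        stationary_populations=pops,
        transition_matrix=matrix,
        noise_sigma=noise_sigma,
        n_frames=n_frames,
        dt=dt,
        seed=seed,
    )


def generate_multistate_trajectory(spec: MultiStateSpec) -> tuple[Trajectory, np.ndarray]:
    """Simulate the Markov-modulated conformational ensemble.

    Frame ``t`` is ``reference_frames[s_t]`` plus i.i.d. Gaussian noise of
    width ``noise_sigma`` on every coordinate, where ``s_t`` follows the
    transition matrix from an initial state drawn from the stationary
    distribution.  Returns the trajectory and the true per-frame labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_states
    labels = np.empty(spec.n_frames, dtype=np.intp)
    cum_rows = np.cumsum(spec.transition_matrix, axis=1)
    labels[0] = np.searchsorted(np.cumsum(spec.stationary_populations), rng.random())
    u = rng.random(spec.n_frames)
    for t in range(1, spec.n_frames):
        labels[t] = np.searchsorted(cum_rows[labels[t - 1]], u[t])
    labels = np.minimum(labels, n - 1)

    refs = np.stack([f.coords for f in spec.reference_frames])
    coords = refs[labels]
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    traj = Trajectory(spec.reference_frames[0].topology, coords, dt=spec.dt)
    return traj, labels


@dataclass(frozen=True)
class TwoDomainFixture:
    """A rigid two-domain construction with known inter-domain dihedral."""

    frame: Frame
    dom1_sel: AtomSelection
    dom2_sel: AtomSelection
    hinge1: tuple[str, int, str]
    hinge2: tuple[str, int, str]
    mc1: np.ndarray
    mc2: np.ndarray
    dihedral_deg: float


def generate_two_domain_frame(dihedral_deg: float, arm_length: float = 10.0) -> TwoDomainFixture:
    """Construct point masses whose inter-domain dihedral is exact.

    Two hinge Cα atoms sit on the x axis; each domain is three equal-mass
    pseudo-atoms whose centroid lies at the arm tip.  The dihedral through
    (MC1, hinge1, hinge2, MC2) equals ``dihedral_deg`` exactly under the
    IUPAC sign convention (cis = 0°, right-handed looking hinge1→hinge2).
    """
    if arm_length <= 0:
        raise ConfigError("arm_length must be positive")
    theta = np.radians(dihedral_deg)
    h1 = np.array([0.0, 0.0, 0.0])
    h2 = np.array([6.0, 0.0, 0.0])
    mc1 = h1 + np.array([-3.0, arm_length, 0.0])
    mc2 = h2 + np.array([3.0, arm_length * np.cos(theta), arm_length * np.sin(theta)])

    # offsets summing to zero: equal-mass centroid sits exactly at the target
    offsets = np.array([[1.0, 0.5, 0.3], [-0.7, -1.0, 0.4], [-0.3, 0.5, -0.7]])

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for chain, center, rid0 in (("A", mc1, 201), ("B", mc2, 201)):
        for k in range(3):
            atoms.append(
                Atom(name="CA", residue_name="GLY", residue_id=rid0 + k, chain_id=chain,
                     element="C", mass=12.011)
            )
            coords.append(center + offsets[k])
    for chain, hpos in (("A", h1), ("B", h2)):
        atoms.append(
            Atom(name="CA", residue_name="HIS", residue_id=205, chain_id=chain,
                 element="C", mass=12.011)
        )
        coords.append(hpos)

    frame = Frame(tuple(atoms), np.asarray(coords))
    dom1 = AtomSelection(chain_ids=frozenset({"A"}), residue_ids=(201, 202, 203))
    dom2 = AtomSelection(chain_ids=frozenset({"B"}), residue_ids=(201, 202, 203))
    return TwoDomainFixture(
        frame=frame,
        dom1_sel=dom1,
        dom2_sel=dom2,
        hinge1=("A", 205, "CA"),
        hinge2=("B", 205, "CA"),
        mc1=mc1,
        mc2=mc2,
        dihedral_deg=dihedral_deg,
    )


@dataclass
class FepSyntheticSpec:
    """Per-window Gaussian AR(1) energy-difference samples with exact ΔG.

    Window ``k`` has marginal Normal(μ_k, σ_k²) in kcal/mol and lag-1
    autocorrelation ``ar1_phi``.  The exact Zwanzig free energy of each
    window is ``μ_k − σ_k²/(2 k_B T)`` (Gaussian closed form), so the exact
    total is known.
    """

    mu: np.ndarray  # kcal/mol, one per window
    sigma: np.ndarray  # kcal/mol, one per window
    ar1_phi: float = 0.0
    n_samples: int = 1000
    temperature: float = 300.0  # K
    seed: int = 0
    endpoint_density: float = 2.0  # λ schedule warping for window metadata

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, float))
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ConfigError("mu and sigma must be 1-d arrays of equal length")
        if np.any(self.sigma < 0):
            raise ConfigError("sigma must be non-negative")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ConfigError("ar1_phi must be in [0, 1)")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")

    @property
    def n_windows(self) -> int:
        return self.mu.shape[0]

    def true_window_dg(self) -> np.ndarray:
        kt = KB_KCAL_PER_MOL_K * self.temperature
        return self.mu - self.sigma**2 / (2.0 * kt)

    def true_total_dg(self) -> float:
        return float(self.true_window_dg().sum())


def generate_fep_samples(spec: FepSyntheticSpec) -> tuple[list[FepWindow], float]:
    """Generate stationary AR(1) ΔU series for every λ window.

    ``x_t = μ + φ (x_{t-1} − μ) + ε_t`` with ``ε_t ~ N(0, σ²(1 − φ²))`` and
    ``x_0`` drawn from the stationary marginal, so every sample has the exact
    Normal(μ, σ²) marginal.  Returns the windows plus the exact total ΔG.
    """
    rng = np.random.default_rng(spec.seed)
    breaks = lambda_schedule(spec.n_windows, spec.endpoint_density)
    phi = spec.ar1_phi
    windows = []
    for k in range(spec.n_windows):
        mu_k = spec.mu[k]
        sd_k = spec.sigma[k]
        z = rng.standard_normal(spec.n_samples)
        if phi > 0 and sd_k > 0:
            x = np.empty(spec.n_samples)
            x[0] = z[0]
            innov = np.sqrt(1.0 - phi * phi)
            for t in range(1, spec.n_samples):
                x[t] = phi * x[t - 1] + innov * z[t]
            series = mu_k + sd_k * x
        else:
            series = mu_k + sd_k * z
        windows.append(
            FepWindow(
                lambda_from=float(breaks[k]),
                lambda_to=float(breaks[k + 1]),
                delta_u=series,
                temperature=spec.temperature,
            )
        )
    return windows, spec.true_total_dg()
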