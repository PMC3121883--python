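"""Free-energy-perturbation estimation with an autocorrelation-aware error model.

Per λ window the Zwanzig (exponential-averaging) estimator gives

    ΔG_k = −k_B T · ln ⟨ exp(−ΔU / k_B T) ⟩

where ΔU = U(x; λ_to) − U(x; λ_from) is sampled from the λ_from ensemble.
The statistical error of each window is first-order (delta-method)
propagation of the standard error of the exponential ensemble average
through the logarithm, with the sample variance inflated by the sampling
ratio (1 + 2τ): τ is the integrated autocorrelation time of the series, so
N/(1 + 2τ) is the effective number of independent samples.  Windows are
treated as independent; totals add and variances add in quadrature.  The
thermodynamic cycle closes as ΔΔG_bind = ΔG_alchemy,bound − ΔG_alchemy,free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from .errors import ConfigError, ContractError, DataError, ScheduleError

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "FepWindow",
    "InefficiencyEstimate",
    "WindowEstimate",
    "FepResult",
    "CycleSpec",
    "zwanzig_window_dg",
    "statistical_inefficiency",
    "window_error",
    "estimate_window",
    "accumulate",
    "combine_windows",
    "lambda_schedule",
    "cycle_ddg",
    "ddg_from_kd",
    "write_windows",
    "read_window_dir",
]

# molar gas constant in kcal/(mol K); used for both per-mole and per-molecule
# forms so the two can never diverge
KB_KCAL_PER_MOL_K = 1.987204e-3


@dataclass
class FepWindow:
    """One λ-pair's ΔU series (kcal/mol), sampled from the λ_from ensemble."""

    lambda_from: float
    lambda_to: float
    delta_u: np.ndarray
    temperature: float = 300.0  # K
    discard: int = 0  # equilibration prefix to drop

    def __post_init__(self) -> None:
        self.delta_u = np.asarray(self.delta_u, float)
        if not (0.0 <= self.lambda_from <= 1.0 and 0.0 <= self.lambda_to <= 1.0):
            raise ConfigError("lambda values must lie in [0, 1]")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if self.discard < 0:
            raise ConfigError("discard must be non-negative")
        if self.samples().size == 0:
            raise DataError("window ΔU series is empty (after discard)")
        if not np.all(np.isfinite(self.delta_u)):
            raise DataError("non-finite ΔU sample")

    def samples(self) -> np.ndarray:
        return self.delta_u[self.discard :]

    @property
    def kt(self) -> float:
        return KB_KCAL_PER_MOL_K * self.temperature


@dataclass(frozen=True)
class InefficiencyEstimate:
    """Integrated autocorrelation time and the (1 + 2τ) sampling ratio."""

    tau: float  # in sample steps
    sampling_ratio: float  # 1 + 2 tau, >= 1
    effective_n: float  # N / (1 + 2 tau)
    degenerate: bool = False  # zero-variance series

    def tau_ps(self, dt: float) -> float:
        """Correlation time in ps for a series sampled every ``dt`` ps."""
        return self.tau * dt


@dataclass(frozen=True)
class WindowEstimate:
    dg: float  # kcal/mol
    sigma: float  # kcal/mol
    inefficiency: InefficiencyEstimate
    n: int
    low_effective_n: bool = False  # effective_n < 10


@dataclass
class FepResult:
    """Per-window free energies and the independence-assumption totals."""

    window_dg: np.ndarray  # kcal/mol
    window_sigma: np.ndarray  # kcal/mol
    temperature: float
    lambda_from: np.ndarray | None = None
    lambda_to: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.window_dg = np.atleast_1d(np.asarray(self.window_dg, float))
        self.window_sigma = np.atleast_1d(np.asarray(self.window_sigma, float))
        if self.window_dg.shape != self.window_sigma.shape:
            raise ContractError("per-window ΔG and σ must align")

    @property
    def total_dg(self) -> float:
        return float(self.window_dg.sum())

    @property
    def total_sigma(self) -> float:
        return float(np.sqrt(np.sum(self.window_sigma**2)))

    @property
    def n_windows(self) -> int:
        return self.window_dg.shape[0]


@dataclass
class CycleSpec:
    """The two alchemical legs of the phosphorylation thermodynamic cycle."""

    bound_leg: FepResult
    free_leg: FepResult

    def __post_init__(self) -> None:
        if abs(self.bound_leg.temperature - self.free_leg.temperature) > 1e-9:
            raise ContractError(
                "bound and free legs must share a temperature "
                f"({self.bound_leg.temperature} K vs {self.free_leg.temperature} K)"
            )


def zwanzig_window_dg(win: FepWindow) -> float:
    """Exponential-averaging free energy of one window (kcal/mol).

    Computed as −k_B T (logsumexp(−ΔU/k_B T) − ln N); the max-shift inside
    logsumexp makes arbitrarily large |ΔU| safe against overflow.
    """
    du = win.samples()
    kt = win.kt
    return float(-kt * (logsumexp(-du / kt) - np.log(du.size)))


def statistical_inefficiency(
    series: np.ndarray, c_threshold: float = 0.05, min_samples: int = 50
) -> InefficiencyEstimate:
    """Integrated autocorrelation time with normalized-autocovariance truncation.

    τ = Σ_{t≥1} C(t)/C(0), summed up to (excluding) the first lag at which
    the normalized autocovariance drops below ``c_threshold``.  A
    zero-variance series returns the degenerate ratio 1.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < min_samples:
        raise DataError(f"need at least {min_samples} samples, got {n}")
    x = x - x.mean()
    c0 = float(np.dot(x, x) / n)
    if c0 <= 0 or not np.isfinite(c0):
        return InefficiencyEstimate(tau=0.0, sampling_ratio=1.0, effective_n=float(n),
                                    degenerate=True)
    tau = 0.0
    for t in range(1, n // 2):
        ct = float(np.dot(x[:-t], x[t:]) / (n - t))
        rho = ct / c0
        if rho < c_threshold:
            break
        tau += rho
    ratio = 1.0 + 2.0 * tau
    return InefficiencyEstimate(tau=tau, sampling_ratio=ratio, effective_n=n / ratio)


def window_error(win: FepWindow, ineff: InefficiencyEstimate | None = None) -> float:
    """First-order statistical error of one window's ΔG (kcal/mol).

    The standard error of the exponential ensemble average m = ⟨e^{−ΔU/kT}⟩,
    inflated by the sampling ratio (1 + 2τ), is pushed through the logarithm:
    σ_ΔG = k_B T · SE(m) / m.  Computed with a common max shift so the ratio
    is overflow-safe.
    """
    du = win.samples()
    if ineff is None:
        if du.size >= 50:
            ineff = statistical_inefficiency(du)
        else:
            ineff = InefficiencyEstimate(tau=0.0, sampling_ratio=1.0,
                                         effective_n=float(du.size))
    logw = -du / win.kt
    shift = logw.max()
    w = np.exp(logw - shift)  # scaling cancels in SE(m)/m
    m = w.mean()
    if du.size < 2:
        return 0.0
    var = w.var(ddof=1)
    se_m = np.sqrt(var * ineff.sampling_ratio / du.size)
    return float(win.kt * se_m / m)


def estimate_window(win: FepWindow) -> WindowEstimate:
    """ΔG, σ and the autocorrelation diagnostics for one window."""
    du = win.samples()
    if du.size >= 50:
        ineff = statistical_inefficiency(du)
    else:
        ineff = InefficiencyEstimate(tau=0.0, sampling_ratio=1.0, effective_n=float(du.size))
    dg = zwanzig_window_dg(win)
    sigma = window_error(win, ineff)
    return WindowEstimate(
        dg=dg,
        sigma=sigma,
        inefficiency=ineff,
        n=int(du.size),
        low_effective_n=ineff.effective_n < 10,
    )


def _check_tiling(windows: list[FepWindow]) -> None:
    if not windows:
        raise DataError("no windows given")
    order = sorted(range(len(windows)), key=lambda i: windows[i].lambda_from)
    ws = [windows[i] for i in order]
    if abs(ws[0].lambda_from) > 1e-9:
        raise ScheduleError(f"schedule must start at λ=0, starts at λ={ws[0].lambda_from}")
    if abs(ws[-1].lambda_to - 1.0) > 1e-9:
        raise ScheduleError(f"schedule must end at λ=1, ends at λ={ws[-1].lambda_to}")
    for a, b in zip(ws[:-1], ws[1:]):
        if abs(a.lambda_to - b.lambda_from) > 1e-9:
            raise ScheduleError(
                f"gap or overlap in λ tiling at breakpoint {a.lambda_to} -> {b.lambda_from}"
            )


def accumulate(windows: list[FepWindow]) -> FepResult:
    """Estimate every window and assemble the leg total.

    Requires the windows to tile [0, 1] contiguously.  Total ΔG is the sum
    of per-window ΔG; the total variance is the sum of per-window variances
    (windows treated as independent observables).
    """
    _check_tiling(windows)
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ContractError(f"windows disagree on temperature: {sorted(temps)}")
    order = sorted(range(len(windows)), key=lambda i: windows[i].lambda_from)
    ws = [windows[i] for i in order]
    estimates = [estimate_window(w) for w in ws]
    flags = [
        f"window {i} ({w.lambda_from:.4f}->{w.lambda_to:.4f}): effective_n < 10"
        for i, (w, e) in enumerate(zip(ws, estimates))
        if e.low_effective_n
    ]
    return FepResult(
        window_dg=np.array([e.dg for e in estimates]),
        window_sigma=np.array([e.sigma for e in estimates]),
        temperature=ws[0].temperature,
        lambda_from=np.array([w.lambda_from for w in ws]),
        lambda_to=np.array([w.lambda_to for w in ws]),
        flags=flags,
    )


def combine_windows(
    window_dg: np.ndarray, window_sigma: np.ndarray, temperature: float = 300.0
) -> FepResult:
    """Assemble a :class:`FepResult` from precomputed per-window values."""
    return FepResult(window_dg=window_dg, window_sigma=window_sigma, temperature=temperature)


def lambda_schedule(n_windows: int, endpoint_density: float = 1.0) -> np.ndarray:
    """λ breakpoints (length ``n_windows + 1``) densified at the endpoints.

    A uniform grid is warped by the symmetric Beta(d, d) CDF: for
    ``endpoint_density`` d > 1 the warp has vanishing slope at 0 and 1, so
    breakpoints concentrate there (narrower windows toward the endpoints,
    where alchemical integrands are steepest); d = 1 recovers the uniform
    grid exactly.
    """
    if n_windows < 1:
        raise ConfigError("n_windows must be >= 1")
    if endpoint_density < 1.0:
        raise ConfigError("endpoint_density must be >= 1")
    grid = np.linspace(0.0, 1.0, n_windows + 1)
    if endpoint_density == 1.0:
        return grid
    breaks = beta_dist.cdf(grid, endpoint_density, endpoint_density)
    breaks[0], breaks[-1] = 0.0, 1.0
    return breaks


def cycle_ddg(cycle: CycleSpec) -> tuple[float, float]:
    """Close the thermodynamic cycle: ΔΔG_bind = ΔG_bound − ΔG_free.

    The two legs are the alchemical transformations in the bound and free
    states; their errors add in quadrature.
    """
    ddg = cycle.bound_leg.total_dg - cycle.free_leg.total_dg
    sigma = float(np.sqrt(cycle.bound_leg.total_sigma**2 + cycle.free_leg.total_sigma**2))
    return ddg, sigma


def ddg_from_kd(kd_a: float, kd_b: float, temperature: float = 300.0) -> float:
    """Binding free-energy difference from two dissociation constants.

    ΔΔG = R T ln(kd_b / kd_a) in kcal/mol; positive when ``kd_b`` binds more
    weakly than ``kd_a``.
    """
    if kd_a <= 0 or kd_b <= 0:
        raise DataError("dissociation constants must be positive")
    if temperature <= 0:
        raise ConfigError("temperature must be positive")
    return float(KB_KCAL_PER_MOL_K * temperature * np.log(kd_b / kd_a))


def write_windows(windows: list[FepWindow], directory: str | PathLike) -> list[Path]:
    """Write one ``window_XXX.csv`` (columns: step, delta_u_kcal) plus a YAML
    sidecar (lambda_from, lambda_to, temperature, discard) per window."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, win in enumerate(windows):
        csv_path = directory / f"window_{k:03d}.csv"
        pd.DataFrame(
            {"step": np.arange(win.delta_u.size), "delta_u_kcal": win.delta_u}
        ).to_csv(csv_path, index=False)
        sidecar = {
            "lambda_from": float(win.lambda_from),
            "lambda_to": float(win.lambda_to),
            "temperature": float(win.temperature),
            "discard": int(win.discard),
        }
        with open(csv_path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh)
        paths.append(csv_path)
    return paths


def read_window_dir(directory: str | PathLike) -> list[FepWindow]:
    """Load every ``*.csv`` + YAML sidecar pair from a window directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise DataError(f"no such window directory: {directory}")
    csv_paths = sorted(directory.glob("*.csv"))
    if not csv_paths:
        raise DataError(f"no window CSV files in {directory}")
    windows = []
    for csv_path in csv_paths:
        sidecar_path = csv_path.with_suffix(".yaml")
        if not sidecar_path.exists():
            raise DataError(f"missing YAML sidecar for {csv_path.name}")
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        table = pd.read_csv(csv_path)
        if "delta_u_kcal" not in table.columns:
            raise DataError(f"{csv_path.name}: missing delta_u_kcal column")
        windows.append(
            FepWindow(
                lambda_from=float(meta["lambda_from"]),
                lambda_to=float(meta["lambda_to"]),
                delta_u=table["delta_u_kcal"].to_numpy(float),
                temperature=float(meta.get("temperature", 300.0)),
                discard=int(meta.get("discard", 0)),
            )
        )
    return windows
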