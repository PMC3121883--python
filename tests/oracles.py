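"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, generic numerical
optimization) and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rmsd_loops(a: np.ndarray, b: np.ndarray) -> float:
    """Plain atom-by-atom RMSD, explicit arithmetic."""
    total = 0.0
    for pa, pb in zip(a, b):
        total += (pa[0] - pb[0]) ** 2 + (pa[1] - pb[1]) ** 2 + (pa[2] - pb[2]) ** 2
    return float(np.sqrt(total / len(a)))


def best_fit_rmsd_search(mobile: np.ndarray, reference: np.ndarray, n_starts: int = 12) -> float:
    """Minimum RMSD over all proper rigid motions, by numerical search over
    rotation vectors (centroids aligned analytically)."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return rmsd_loops(p @ r.T, q)

    rng = np.random.default_rng(0)
    best = np.inf
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def two_selection_rmsd_pair(
    fit_mobile: np.ndarray,
    fit_reference: np.ndarray,
    eval_mobile: np.ndarray,
    eval_reference: np.ndarray,
) -> float:
    """Fit-on-A / evaluate-on-B RMSD via scipy's Kabsch (align_vectors)."""
    cm_m = fit_mobile.mean(axis=0)
    cm_r = fit_reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(fit_reference - cm_r, fit_mobile - cm_m)
    moved = rot.apply(eval_mobile - cm_m) + cm_r
    return rmsd_loops(moved, eval_reference)


def gromos_brute_force(dist: np.ndarray, cutoff: float) -> tuple[list[int], list[int]]:
    """Exhaustive greedy maximum-neighbor clustering with lowest-index
    tie-break; labels renumbered by decreasing size (formation order on
    ties).  Returns (labels 1-based, center indices by final numbering)."""
    n = dist.shape[0]
    unassigned = set(range(n))
    labels = [0] * n
    formed: list[tuple[int, int]] = []  # (center, size)
    while unassigned:
        best_i, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if j != i and dist[i, j] <= cutoff)
            if count > best_count:
                best_i, best_count = i, count
        members = {j for j in unassigned if j != best_i and dist[best_i, j] <= cutoff}
        members.add(best_i)
        formed.append((best_i, len(members)))
        for j in members:
            labels[j] = len(formed)
        unassigned -= members
    order = sorted(range(len(formed)), key=lambda c: (-formed[c][1], c))
    remap = {old + 1: new + 1 for new, old in enumerate(order)}
    return [remap[l] for l in labels], [formed[c][0] for c in order]


def gaussian_zwanzig_quadrature(mu: float, sigma: float, kt: float) -> float:
    """−kT ln ∫ e^{−u/kT} N(u; μ, σ²) du by numerical quadrature."""

    def integrand(u):
        return np.exp(-u / kt) * np.exp(-((u - mu) ** 2) / (2 * sigma**2)) / (
            sigma * np.sqrt(2 * np.pi)
        )

    val, _ = quad(integrand, mu - 30 * sigma, mu + 30 * sigma, limit=200)
    return float(-kt * np.log(val))
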