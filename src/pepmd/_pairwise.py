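"""Numba kernel for the all-pairs two-selection RMSD matrix.

For every conformation pair (i, j) the optimal proper rotation superposing
j's fit atoms onto i's is found with the quaternion characteristic-
polynomial method (Horn superposition; Newton on the quartic for the largest
eigenvalue of the 4x4 key matrix, eigenvector from cofactors).  The RMSD is
then evaluated over a *different* atom selection under that same transform.
This avoids any per-pair LAPACK call, which is what makes 1e8-pair matrices
tractable on one core.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pairwise_two_selection_rmsd"]


@njit(cache=True, fastmath=True, boundscheck=False)
def _fill_pairwise(fitc, evalrel, ge, out):  # pragma: no cover - numba
    n, nf, _ = fitc.shape
    ne = evalrel.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            sxx = 0.0; sxy = 0.0; sxz = 0.0
            syx = 0.0; syy = 0.0; syz = 0.0
            szx = 0.0; szy = 0.0; szz = 0.0
            ga = 0.0; gb = 0.0
            for a in range(nf):
                px = fitc[j, a, 0]; py = fitc[j, a, 1]; pz = fitc[j, a, 2]
                qx = fitc[i, a, 0]; qy = fitc[i, a, 1]; qz = fitc[i, a, 2]
                ga += px * px + py * py + pz * pz
                gb += qx * qx + qy * qy + qz * qz
                sxx += px * qx; sxy += px * qy; sxz += px * qz
                syx += py * qx; syy += py * qy; syz += py * qz
                szx += pz * qx; szy += pz * qy; szz += pz * qz
            k00 = sxx + syy + szz; k01 = syz - szy; k02 = szx - sxz; k03 = sxy - syx
            k11 = sxx - syy - szz; k12 = sxy + syx; k13 = szx + sxz
            k22 = -sxx + syy - szz; k23 = syz + szy
            k33 = -sxx - syy + szz
            c2 = -2.0 * (sxx * sxx + sxy * sxy + sxz * sxz
                         + syx * syx + syy * syy + syz * syz
                         + szx * szx + szy * szy + szz * szz)
            det_a = (sxx * (syy * szz - syz * szy)
                     - sxy * (syx * szz - syz * szx)
                     + sxz * (syx * szy - syy * szx))
            c1 = -8.0 * det_a
            m0 = k11 * (k22 * k33 - k23 * k23) - k12 * (k12 * k33 - k23 * k13) \
                + k13 * (k12 * k23 - k22 * k13)
            m1 = k01 * (k22 * k33 - k23 * k23) - k12 * (k02 * k33 - k23 * k03) \
                + k13 * (k02 * k23 - k22 * k03)
            m2 = k01 * (k12 * k33 - k23 * k13) - k11 * (k02 * k33 - k23 * k03) \
                + k13 * (k02 * k13 - k12 * k03)
            m3 = k01 * (k12 * k23 - k22 * k13) - k11 * (k02 * k23 - k22 * k03) \
                + k12 * (k02 * k13 - k12 * k03)
            c0 = k00 * m0 - k01 * m1 + k02 * m2 - k03 * m3
            # Newton from the upper bound (GA+GB)/2 onto the largest root
            lam = 0.5 * (ga + gb)
            for _ in range(60):
                lam2 = lam * lam
                f = lam2 * lam2 + c2 * lam2 + c1 * lam + c0
                df = 4.0 * lam2 * lam + 2.0 * c2 * lam + c1
                if df == 0.0:
                    break
                step = f / df
                lam -= step
                if -1e-12 * (1.0 + abs(lam)) < step < 1e-12 * (1.0 + abs(lam)):
                    break
            a00 = k00 - lam; a11 = k11 - lam; a22 = k22 - lam; a33 = k33 - lam
            a01 = k01; a02 = k02; a03 = k03; a12 = k12; a13 = k13; a23 = k23
            # eigenvector = adjugate column; cofactors along row 0 first
            q0 = (a11 * (a22 * a33 - a23 * a23) - a12 * (a12 * a33 - a23 * a13)
                  + a13 * (a12 * a23 - a22 * a13))
            q1 = -(a01 * (a22 * a33 - a23 * a23) - a12 * (a02 * a33 - a23 * a03)
                   + a13 * (a02 * a23 - a22 * a03))
            q2 = (a01 * (a12 * a33 - a23 * a13) - a11 * (a02 * a33 - a23 * a03)
                  + a13 * (a02 * a13 - a12 * a03))
            q3 = -(a01 * (a12 * a23 - a22 * a13) - a11 * (a02 * a23 - a22 * a03)
                   + a12 * (a02 * a13 - a12 * a03))
            nq = q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3
            if nq < 1e-11 * (lam * lam + 1.0):
                q0 = -(a01 * (a22 * a33 - a23 * a23) - a02 * (a12 * a33 - a13 * a23)
                       + a03 * (a12 * a23 - a13 * a22))
                q1 = (a00 * (a22 * a33 - a23 * a23) - a02 * (a02 * a33 - a03 * a23)
                      + a03 * (a02 * a23 - a03 * a22))
                q2 = -(a00 * (a12 * a33 - a13 * a23) - a01 * (a02 * a33 - a03 * a23)
                       + a03 * (a02 * a13 - a03 * a12))
                q3 = (a00 * (a12 * a23 - a13 * a22) - a01 * (a02 * a23 - a03 * a22)
                      + a02 * (a02 * a13 - a03 * a12))
                nq = q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3
            if nq < 1e-300:
                q0 = 1.0; q1 = 0.0; q2 = 0.0; q3 = 0.0; nq = 1.0
            inv = 1.0 / np.sqrt(nq)
            w = q0 * inv; x = q1 * inv; y = q2 * inv; z = q3 * inv
            r00 = 1.0 - 2.0 * (y * y + z * z); r01 = 2.0 * (x * y - w * z)
            r02 = 2.0 * (x * z + w * y)
            r10 = 2.0 * (x * y + w * z); r11 = 1.0 - 2.0 * (x * x + z * z)
            r12 = 2.0 * (y * z - w * x)
            r20 = 2.0 * (x * z - w * y); r21 = 2.0 * (y * z + w * x)
            r22 = 1.0 - 2.0 * (x * x + y * y)
            b00 = 0.0; b01 = 0.0; b02 = 0.0
            b10 = 0.0; b11 = 0.0; b12 = 0.0
            b20 = 0.0; b21 = 0.0; b22 = 0.0
            for a in range(ne):
                px = evalrel[j, a, 0]; py = evalrel[j, a, 1]; pz = evalrel[j, a, 2]
                qx = evalrel[i, a, 0]; qy = evalrel[i, a, 1]; qz = evalrel[i, a, 2]
                b00 += px * qx; b01 += px * qy; b02 += px * qz
                b10 += py * qx; b11 += py * qy; b12 += py * qz
                b20 += pz * qx; b21 += pz * qy; b22 += pz * qz
            # sum_a q_a . (R p_a) = sum_kl R[l,k] B[k,l]
            t = (r00 * b00 + r01 * b10 + r02 * b20
                 + r10 * b01 + r11 * b11 + r12 * b21
                 + r20 * b02 + r21 * b12 + r22 * b22)
            msd = (ge[i] + ge[j] - 2.0 * t) / ne
            if msd < 0.0:
                msd = 0.0
            d = np.sqrt(msd)
            out[i, j] = d
            out[j, i] = d


def pairwise_two_selection_rmsd(
    fit_coords: np.ndarray, eval_coords: np.ndarray, dtype=np.float64
) -> np.ndarray:
    """All-pairs RMSD with fit on one selection, evaluation on another.

    ``fit_coords``: (n, n_fit_atoms, 3); ``eval_coords``: (n, n_eval_atoms,
    3), same conformation order.  Entry (i, j) is the RMSD over the eval
    atoms after the least-RMSD superposition of j's fit atoms onto i's.  The
    result is exactly symmetric (the inverse transform yields the same
    deviations) with a zero diagonal.

    All arithmetic is double precision; ``dtype`` only controls the storage
    of the (n, n) result.  float32 storage halves the footprint of very
    large matrices (~1.6 GB at n = 20,000) at a ~1e-7 relative rounding
    cost, far below any clustering cutoff scale.
    """
    fit_coords = np.ascontiguousarray(fit_coords, dtype=np.float64)
    eval_coords = np.ascontiguousarray(eval_coords, dtype=np.float64)
    cm = fit_coords.mean(axis=1, keepdims=True)
    fitc = fit_coords - cm
    evalrel = np.ascontiguousarray(eval_coords - cm)
    ge = np.ascontiguousarray((evalrel**2).sum(axis=(1, 2)))
    n = fit_coords.shape[0]
    out = np.zeros((n, n), dtype=dtype)
    _fill_pairwise(fitc, evalrel, ge, out)
    return out
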