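"""Vectorised 2TC forward kernels (numba).

These mirror :func:`simbapet.kinetics.convolve_exponential` /
``predict_tac`` but evaluate whole batches of TACs at once; they are the hot
path of both the NLS objective and the HMC log-posterior.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# AIF parameter row layout used throughout: [t0, b, tp, A1, A2, A3, l1, l2, l3]
AIF_NCOL = 9


@njit(cache=True)
def _conv_exp(theta, t, p):
    """Closed-form (AIF (x) exp(-theta s))(t) for one time point."""
    t0 = p[0]
    b = p[1]
    tp = p[2]
    if t <= t0:
        return 0.0
    U = min(t, tp) - t0
    D = t - tp
    if D < 0.0:
        D = 0.0
    if theta > 1e-12:
        eD = np.exp(-theta * D)
        eF = np.exp(-theta * (t - t0))
        out = b * (U * eD / theta - (eD - eF) / (theta * theta))
    else:
        out = 0.5 * b * U * U
    if t > tp:
        for i in range(3):
            A = p[3 + i]
            lam = p[6 + i]
            Ap = A * np.exp(-lam * (tp - t0))
            if theta > 1e-12:
                d = theta - lam
                if abs(d) < 1e-9:
                    out += Ap * D * np.exp(-theta * D)
                else:
                    out += Ap * (np.exp(-lam * D) - np.exp(-theta * D)) / d
            else:
                out += Ap * (1.0 - np.exp(-lam * D)) / lam
    return out


@njit(cache=True)
def tissue_batch(K1, k2, k3, k4, tmid, aifp, aif_idx, out):
    """Tissue curves (IRF (x) AIF) for N TACs at F midpoints -> out (F, N)."""
    N = K1.shape[0]
    F = tmid.shape[0]
    for n in range(N):
        s = k2[n] + k3[n] + k4[n]
        disc = s * s - 4.0 * k2[n] * k4[n]
        if disc < 0.0:
            disc = 0.0
        root = np.sqrt(disc)
        th1 = 0.5 * (s + root)
        th2 = 0.5 * (s - root)
        if th1 - th2 < 1e-6:
            mid = 0.5 * (th1 + th2)
            th1 = mid + 5e-7
            th2 = mid - 5e-7
        c = k3[n] + k4[n]
        phi1 = K1[n] * (th1 - c) / (th1 - th2)
        phi2 = K1[n] * (c - th2) / (th1 - th2)
        p = aifp[aif_idx[n]]
        for i in range(F):
            t = tmid[i]
            out[i, n] = phi1 * _conv_exp(th1, t, p) + phi2 * _conv_exp(th2, t, p)
    return out


@njit(cache=True)
def tac_batch(K1, VND, BPND, k4, vB, tmid, aifp, aif_idx, cb, out):
    """Full model prediction (F, N) from outcome-parameterised inputs.

    cb is (F, N) whole-blood frame means; out receives
    (1-vB)*tissue + vB*cb.
    """
    k2 = K1 / VND
    k3 = BPND * k4
    tissue_batch(K1, k2, k3, k4, tmid, aifp, aif_idx, out)
    N = K1.shape[0]
    F = tmid.shape[0]
    for n in range(N):
        for i in range(F):
            out[i, n] = (1.0 - vB[n]) * out[i, n] + vB[n] * cb[i, n]
    return out


@njit(cache=True)
def _tissue_one(K1, k2, k3, k4, tmid, p, out):
    """Tissue curve for one TAC into out (F,)."""
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0.0:
        disc = 0.0
    root = np.sqrt(disc)
    th1 = 0.5 * (s + root)
    th2 = 0.5 * (s - root)
    if th1 - th2 < 1e-6:
        mid = 0.5 * (th1 + th2)
        th1 = mid + 5e-7
        th2 = mid - 5e-7
    c = k3 + k4
    phi1 = K1 * (th1 - c) / (th1 - th2)
    phi2 = K1 * (c - th2) / (th1 - th2)
    for i in range(tmid.shape[0]):
        out[i] = phi1 * _conv_exp(th1, tmid[i], p) + phi2 * _conv_exp(th2, tmid[i], p)


@njit(cache=True)
def model_core(eta, eta_vb, gbase, ft, wstar, y, mask, cb, tmid, aifp, aif_idx, fd_h):
    """Fused likelihood + data-side gradients of the hierarchical model.

    eta: (N,4) log (K1, VND, BPND, k4); eta_vb: (N,) log vB;
    gbase: (N,) per-TAC log-error offset (intercept + covariates + subject +
    region terms); ft: (F,) smooth time component; wstar: (F,N) fixed offset.

    Returns (ok, lp, Geta (N,4), Geta_vb (N,), Gg_tac (N,), Gf (F,)) where the
    G arrays are d lp/d eta etc.  ok=False signals an out-of-range point.
    """
    F = tmid.shape[0]
    N = eta.shape[0]
    Geta = np.zeros((N, 4))
    Geta_vb = np.zeros(N)
    Gg_tac = np.zeros(N)
    Gf = np.zeros(F)
    lp = 0.0
    eh = np.exp(fd_h)
    T = np.empty(F)
    Tp = np.empty(F)
    for n in range(N):
        for q in range(4):
            if abs(eta[n, q]) > 12.0:
                return False, 0.0, Geta, Geta_vb, Gg_tac, Gf
        if abs(eta_vb[n]) > 12.0:
            return False, 0.0, Geta, Geta_vb, Gg_tac, Gf
        K1 = np.exp(eta[n, 0])
        VND = np.exp(eta[n, 1])
        BPND = np.exp(eta[n, 2])
        k4 = np.exp(eta[n, 3])
        vB = np.exp(eta_vb[n])
        k2 = K1 / VND
        k3 = BPND * k4
        p = aifp[aif_idx[n]]
        _tissue_one(K1, k2, k3, k4, tmid, p, T)

        # residuals and error-model gradient
        gmu = np.empty(F)
        for i in range(F):
            g = gbase[n] + ft[i] + wstar[i, n]
            if abs(g) > 30.0:
                return False, 0.0, Geta, Geta_vb, Gg_tac, Gf
            if mask[i, n] > 0.0:
                sig = np.exp(g)
                r = y[i, n] - ((1.0 - vB) * T[i] + vB * cb[i, n])
                z2 = (r / sig) ** 2
                lp += -0.5 * z2 - g
                gmu[i] = r / (sig * sig)
                gg = z2 - 1.0
                Gg_tac[n] += gg
                Gf[i] += gg
                Geta_vb[n] += gmu[i] * vB * (cb[i, n] - T[i])
            else:
                gmu[i] = 0.0

        # forward differences through the 2TC map
        for q in range(4):
            if q == 0:
                _tissue_one(K1 * eh, k2 * eh, k3, k4, tmid, p, Tp)
            elif q == 1:
                _tissue_one(K1, k2 / eh, k3, k4, tmid, p, Tp)
            elif q == 2:
                _tissue_one(K1, k2, k3 * eh, k4, tmid, p, Tp)
            else:
                _tissue_one(K1, k2, k3 * eh, k4 * eh, tmid, p, Tp)
            acc = 0.0
            for i in range(F):
                acc += gmu[i] * (Tp[i] - T[i])
            Geta[n, q] = acc * (1.0 - vB) / fd_h
    return True, lp, Geta, Geta_vb, Gg_tac, Gf


def aif_row(aif) -> np.ndarray:
    """Pack an AIFParameters object into the kernel row layout."""
    return np.array(
        [aif.t0, aif.b, aif.tp, aif.A1, aif.A2, aif.A3, aif.lambda1, aif.lambda2, aif.lambda3],
        dtype=float,
    )
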