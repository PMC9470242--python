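"""Fully jitted log-posterior gradients for the hierarchical models.

The samplers call these at ~1e5 evaluations per fit, so the entire
computation -- non-centred hierarchy assembly, the 2TC forward map with its
forward-difference derivatives, the error model, all priors and the
backpropagation -- runs inside one numba kernel per model.  The Python-side
classes in :mod:`simbapet._model` only pack data and delegate here.

Block offsets (``offs``) index the unconstrained vector in a fixed order:

  0 alpha | 1 d_K1 | 2 d_BPND | 3-8 beta_{K1,VND,BPND,k4,vB,sigma} |
  9-14 log_sd_{subject,region,tac,vB,sigma,smooth} |
  15-17 corr_{subject,region,tac} (empty when univariate) |
  18 z_subject | 19 z_region | 20 z_tac | 21 z_vB_subject | 22 z_vB_region |
  23 z_sigma_subject | 24 z_sigma_region | 25 gamma | 26 total dim
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._forward import model_core


@njit(cache=True)
def cpc_chol(z: np.ndarray, d: int) -> np.ndarray:
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, d):
        s = 0.0
        for j in range(i):
            L[i, j] = z[idx] * np.sqrt(max(1.0 - s, 0.0))
            s += L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(1.0 - s, 0.0))
    return L


@njit(cache=True)
def chol_jac(y: np.ndarray, d: int):
    """L(tanh(y)), tanh(y), and dL/dy by central differences."""
    z = np.tanh(y)
    L = cpc_chol(z, d)
    jac = np.zeros((d, d, y.size))
    h = 1e-7
    for c in range(y.size):
        yp = y.copy()
        yp[c] += h
        ym = y.copy()
        ym[c] -= h
        jac[:, :, c] = (cpc_chol(np.tanh(yp), d) - cpc_chol(np.tanh(ym), d)) / (2 * h)
    return L, z, jac


@njit(cache=True)
def simba_logp_grad(x, offs, J, K, N, multivariate,
                    si, ri,
                    XK1, XVND, XBPND, Xk4, XvB, Xsig,
                    B, wstar, y, mask, cb, tmid, aifp, aif_idx,
                    norm_loc, norm_scale, sd_scales, lkj_b, fd_h):
    dim = offs[26]
    grad = np.zeros(dim)
    F = tmid.shape[0]

    alpha = x[offs[0]:offs[0] + 6]
    dK1 = x[offs[1]:offs[2]]
    dBP = x[offs[2]:offs[3]]
    ls_subj = x[offs[9]:offs[9] + 4]
    ls_reg = x[offs[10]:offs[10] + 2]
    ls_tac = x[offs[11]:offs[11] + 4]
    ls_vb = x[offs[12]:offs[12] + 2]
    ls_sg = x[offs[13]:offs[13] + 2]
    ls_f = x[offs[14]]
    z_subj = x[offs[18]:offs[19]].reshape(J, 4)
    z_reg = x[offs[19]:offs[20]].reshape(K, 2)
    z_tac = x[offs[20]:offs[21]].reshape(N, 4)
    z_vb_s = x[offs[21]:offs[22]]
    z_vb_r = x[offs[22]:offs[23]]
    z_sg_s = x[offs[23]:offs[24]]
    z_sg_r = x[offs[24]:offs[25]]
    gamma_raw = x[offs[25]:offs[26]]

    s_subj = np.exp(ls_subj)
    s_reg = np.exp(ls_reg)
    s_tac = np.exp(ls_tac)
    s_vb = np.exp(ls_vb)
    s_sg = np.exp(ls_sg)
    s_f = np.exp(ls_f)

    if multivariate:
        L_subj, zc_subj, J_subj = chol_jac(x[offs[15]:offs[15] + 6], 4)
        L_reg, zc_reg, J_reg = chol_jac(x[offs[16]:offs[16] + 1], 2)
        L_tac, zc_tac, J_tac = chol_jac(x[offs[17]:offs[17] + 6], 4)
    else:
        L_subj = np.eye(4)
        L_reg = np.eye(2)
        L_tac = np.eye(4)
        zc_subj = np.zeros(6)
        zc_reg = np.zeros(1)
        zc_tac = np.zeros(6)
        J_subj = np.zeros((4, 4, 6))
        J_reg = np.zeros((2, 2, 1))
        J_tac = np.zeros((4, 4, 6))

    tau = np.empty((J, 4))
    for j in range(J):
        for p in range(4):
            acc = 0.0
            for q in range(p + 1):
                acc += L_subj[p, q] * z_subj[j, q]
            tau[j, p] = s_subj[p] * acc
    ups = np.empty((K, 2))
    for k in range(K):
        for p in range(2):
            acc = 0.0
            for q in range(p + 1):
                acc += L_reg[p, q] * z_reg[k, q]
            ups[k, p] = s_reg[p] * acc
    phi = np.empty((N, 4))
    for n in range(N):
        for p in range(4):
            acc = 0.0
            for q in range(p + 1):
                acc += L_tac[p, q] * z_tac[n, q]
            phi[n, p] = s_tac[p] * acc

    eta = np.empty((N, 4))
    eta_vb = np.empty(N)
    gbase = np.empty(N)
    bK1 = x[offs[3]:offs[4]]
    bVND = x[offs[4]:offs[5]]
    bBP = x[offs[5]:offs[6]]
    bk4 = x[offs[6]:offs[7]]
    bvB = x[offs[7]:offs[8]]
    bsig = x[offs[8]:offs[9]]
    for n in range(N):
        j = si[n]
        k = ri[n]
        e0 = alpha[0] + tau[j, 0] + phi[n, 0]
        e1 = alpha[1] + tau[j, 1] + ups[k, 0] + phi[n, 1]
        e2 = alpha[2] + tau[j, 2] + phi[n, 2]
        e3 = alpha[3] + tau[j, 3] + ups[k, 1] + phi[n, 3]
        if k > 0:
            e0 += dK1[k - 1]
            e2 += dBP[k - 1]
        for c in range(XK1.shape[1]):
            e0 += XK1[n, c] * bK1[c]
        for c in range(XVND.shape[1]):
            e1 += XVND[n, c] * bVND[c]
        for c in range(XBPND.shape[1]):
            e2 += XBPND[n, c] * bBP[c]
        for c in range(Xk4.shape[1]):
            e3 += Xk4[n, c] * bk4[c]
        eta[n, 0] = e0
        eta[n, 1] = e1
        eta[n, 2] = e2
        eta[n, 3] = e3
        ev = alpha[4] + s_vb[0] * z_vb_s[j] + s_vb[1] * z_vb_r[k]
        for c in range(XvB.shape[1]):
            ev += XvB[n, c] * bvB[c]
        eta_vb[n] = ev
        gb = alpha[5] + s_sg[0] * z_sg_s[j] + s_sg[1] * z_sg_r[k]
        for c in range(Xsig.shape[1]):
            gb += Xsig[n, c] * bsig[c]
        gbase[n] = gb

    nb = gamma_raw.shape[0]
    gamma = gamma_raw * s_f
    ft = np.zeros(F)
    for i in range(F):
        for m in range(nb):
            ft[i] += B[i, m] * gamma[m]

    ok, lp, Geta, Geta_vb, Gg_tac, Gf = model_core(
        eta, eta_vb, gbase, ft, wstar, y, mask, cb, tmid, aifp, aif_idx, fd_h)
    if not ok:
        return -np.inf, grad

    # ---- backprop ----
    ga = grad[offs[0]:offs[0] + 6]
    gdK1 = grad[offs[1]:offs[2]]
    gdBP = grad[offs[2]:offs[3]]
    gz_subj = grad[offs[18]:offs[19]].reshape(J, 4)
    gz_reg = grad[offs[19]:offs[20]].reshape(K, 2)
    gz_tac = grad[offs[20]:offs[21]].reshape(N, 4)
    gz_vb_s = grad[offs[21]:offs[22]]
    gz_vb_r = grad[offs[22]:offs[23]]
    gz_sg_s = grad[offs[23]:offs[24]]
    gz_sg_r = grad[offs[24]:offs[25]]
    ggamma = grad[offs[25]:offs[26]]
    gls_subj = grad[offs[9]:offs[9] + 4]
    gls_reg = grad[offs[10]:offs[10] + 2]
    gls_tac = grad[offs[11]:offs[11] + 4]
    gls_vb = grad[offs[12]:offs[12] + 2]
    gls_sg = grad[offs[13]:offs[13] + 2]

    Tsub = np.zeros((J, 4))
    Treg = np.zeros((K, 2))
    TvB_s = np.zeros(J)
    TvB_r = np.zeros(K)
    Tsg_s = np.zeros(J)
    Tsg_r = np.zeros(K)
    gbK1 = grad[offs[3]:offs[4]]
    gbVND = grad[offs[4]:offs[5]]
    gbBP = grad[offs[5]:offs[6]]
    gbk4 = grad[offs[6]:offs[7]]
    gbvB = grad[offs[7]:offs[8]]
    gbsig = grad[offs[8]:offs[9]]
    for n in range(N):
        j = si[n]
        k = ri[n]
        for p in range(4):
            ga[p] += Geta[n, p]
            Tsub[j, p] += Geta[n, p]
        ga[4] += Geta_vb[n]
        ga[5] += Gg_tac[n]
        Treg[k, 0] += Geta[n, 1]
        Treg[k, 1] += Geta[n, 3]
        TvB_s[j] += Geta_vb[n]
        TvB_r[k] += Geta_vb[n]
        Tsg_s[j] += Gg_tac[n]
        Tsg_r[k] += Gg_tac[n]
        if k > 0:
            gdK1[k - 1] += Geta[n, 0]
            gdBP[k - 1] += Geta[n, 2]
        for c in range(XK1.shape[1]):
            gbK1[c] += XK1[n, c] * Geta[n, 0]
        for c in range(XVND.shape[1]):
            gbVND[c] += XVND[n, c] * Geta[n, 1]
        for c in range(XBPND.shape[1]):
            gbBP[c] += XBPND[n, c] * Geta[n, 2]
        for c in range(Xk4.shape[1]):
            gbk4[c] += Xk4[n, c] * Geta[n, 3]
        for c in range(XvB.shape[1]):
            gbvB[c] += XvB[n, c] * Geta_vb[n]
        for c in range(Xsig.shape[1]):
            gbsig[c] += Xsig[n, c] * Gg_tac[n]

    # hierarchy blocks: deviation = s * L * z
    GLsub = np.zeros((4, 4))
    for j in range(J):
        for p in range(4):
            t = Tsub[j, p] * s_subj[p]
            gls_subj[p] += Tsub[j, p] * tau[j, p]
            for q in range(p + 1):
                gz_subj[j, q] += t * L_subj[p, q]
                GLsub[p, q] += t * z_subj[j, q]
    GLreg = np.zeros((2, 2))
    for k in range(K):
        for p in range(2):
            t = Treg[k, p] * s_reg[p]
            gls_reg[p] += Treg[k, p] * ups[k, p]
            for q in range(p + 1):
                gz_reg[k, q] += t * L_reg[p, q]
                GLreg[p, q] += t * z_reg[k, q]
    GLtac = np.zeros((4, 4))
    for n in range(N):
        for p in range(4):
            t = Geta[n, p] * s_tac[p]
            gls_tac[p] += Geta[n, p] * phi[n, p]
            for q in range(p + 1):
                gz_tac[n, q] += t * L_tac[p, q]
                GLtac[p, q] += t * z_tac[n, q]

    for j in range(J):
        gz_vb_s[j] += TvB_s[j] * s_vb[0]
        gls_vb[0] += TvB_s[j] * s_vb[0] * z_vb_s[j]
        gz_sg_s[j] += Tsg_s[j] * s_sg[0]
        gls_sg[0] += Tsg_s[j] * s_sg[0] * z_sg_s[j]
    for k in range(K):
        gz_vb_r[k] += TvB_r[k] * s_vb[1]
        gls_vb[1] += TvB_r[k] * s_vb[1] * z_vb_r[k]
        gz_sg_r[k] += Tsg_r[k] * s_sg[1]
        gls_sg[1] += Tsg_r[k] * s_sg[1] * z_sg_r[k]

    gls_f = 0.0
    for m in range(nb):
        acc = 0.0
        for i in range(F):
            acc += B[i, m] * Gf[i]
        ggamma[m] += acc * s_f
        gls_f += acc * gamma[m]
    grad[offs[14]] += gls_f

    if multivariate:
        gy = grad[offs[15]:offs[15] + 6]
        for c in range(6):
            acc = 0.0
            for a in range(4):
                for b_ in range(a + 1):
                    acc += GLsub[a, b_] * J_subj[a, b_, c]
            gy[c] += acc
        gy = grad[offs[16]:offs[16] + 1]
        acc = 0.0
        for a in range(2):
            for b_ in range(a + 1):
                acc += GLreg[a, b_] * J_reg[a, b_, 0]
        gy[0] += acc
        gy = grad[offs[17]:offs[17] + 6]
        for c in range(6):
            acc = 0.0
            for a in range(4):
                for b_ in range(a + 1):
                    acc += GLtac[a, b_] * J_tac[a, b_, c]
            gy[c] += acc

    # ---- priors ----
    for i in range(offs[9]):
        rr = (x[i] - norm_loc[i]) / norm_scale[i]
        lp += -0.5 * rr * rr
        grad[i] += -rr / norm_scale[i]
    for i in range(15):
        ii = offs[9] + i
        uu = np.exp(2.0 * x[ii]) / (3.0 * sd_scales[i] ** 2)
        lp += -2.0 * np.log1p(uu) + x[ii]
        grad[ii] += 1.0 - 4.0 * uu / (1.0 + uu)
    if multivariate:
        zall = np.concatenate((zc_subj, zc_reg, zc_tac))
        for i in range(13):
            lp += lkj_b[i] * np.log1p(-zall[i] * zall[i])
            grad[offs[15] + i] += -2.0 * lkj_b[i] * zall[i]
    for i in range(offs[18], dim):
        lp += -0.5 * x[i] * x[i]
        grad[i] += -x[i]

    if not np.isfinite(lp):
        return -np.inf, np.zeros(dim)
    return lp, grad


@njit(cache=True)
def values_logp_grad(x, offs, J, K, N, multivariate,
                     si, ri, V,
                     XK1, XVND, XBPND, Xk4,
                     norm_loc, norm_scale, sd_scales, lkj_b):
    """Fit-to-values model: multifactor mean structure with a TAC-level
    multivariate normal residual.  Block offsets:

      0 alpha(4) | 1 d_K1 | 2 d_BPND | 3-6 beta_{K1,VND,BPND,k4} |
      7-9 log_sd_{subject,region,tac} | 10-12 corr_{subject,region,tac} |
      13 z_subject | 14 z_region | 15 total dim
    """
    dim = offs[15]
    grad = np.zeros(dim)

    alpha = x[offs[0]:offs[0] + 4]
    dK1 = x[offs[1]:offs[2]]
    dBP = x[offs[2]:offs[3]]
    bK1 = x[offs[3]:offs[4]]
    bVND = x[offs[4]:offs[5]]
    bBP = x[offs[5]:offs[6]]
    bk4 = x[offs[6]:offs[7]]
    ls_subj = x[offs[7]:offs[7] + 4]
    ls_reg = x[offs[8]:offs[8] + 2]
    ls_tac = x[offs[9]:offs[9] + 4]
    z_subj = x[offs[13]:offs[14]].reshape(J, 4)
    z_reg = x[offs[14]:offs[15]].reshape(K, 2)

    for i in range(4):
        if abs(ls_tac[i]) > 8.0:
            return -np.inf, grad
    s_subj = np.exp(ls_subj)
    s_reg = np.exp(ls_reg)
    s_tac = np.exp(ls_tac)

    if multivariate:
        for i in range(offs[10], offs[13]):
            if abs(x[i]) > 9.0:
                return -np.inf, grad
        L_subj, zc_subj, J_subj = chol_jac(x[offs[10]:offs[10] + 6], 4)
        L_reg, zc_reg, J_reg = chol_jac(x[offs[11]:offs[11] + 1], 2)
        L_tac, zc_tac, J_tac = chol_jac(x[offs[12]:offs[12] + 6], 4)
    else:
        L_subj = np.eye(4)
        L_reg = np.eye(2)
        L_tac = np.eye(4)
        zc_subj = np.zeros(6)
        zc_reg = np.zeros(1)
        zc_tac = np.zeros(6)
        J_subj = np.zeros((4, 4, 6))
        J_reg = np.zeros((2, 2, 1))
        J_tac = np.zeros((4, 4, 6))

    # M = diag(s_tac) L_tac, residual covariance Sigma = M M^T
    M = np.zeros((4, 4))
    for a in range(4):
        for b_ in range(a + 1):
            M[a, b_] = s_tac[a] * L_tac[a, b_]
        if M[a, a] < 1e-10:
            return -np.inf, grad

    tau = np.empty((J, 4))
    for j in range(J):
        for p in range(4):
            acc = 0.0
            for q in range(p + 1):
                acc += L_subj[p, q] * z_subj[j, q]
            tau[j, p] = s_subj[p] * acc
    ups = np.empty((K, 2))
    for k in range(K):
        for p in range(2):
            acc = 0.0
            for q in range(p + 1):
                acc += L_reg[p, q] * z_reg[k, q]
            ups[k, p] = s_reg[p] * acc

    # residuals and likelihood via forward/backward triangular solves
    lp = 0.0
    logdet = 0.0
    for a in range(4):
        logdet += np.log(M[a, a])
    lp += -N * logdet
    r = np.empty((N, 4))
    Geta = np.empty((N, 4))
    w = np.empty(4)
    for n in range(N):
        j = si[n]
        k = ri[n]
        m0 = alpha[0] + tau[j, 0]
        m1 = alpha[1] + tau[j, 1] + ups[k, 0]
        m2 = alpha[2] + tau[j, 2]
        m3 = alpha[3] + tau[j, 3] + ups[k, 1]
        if k > 0:
            m0 += dK1[k - 1]
            m2 += dBP[k - 1]
        for c in range(XK1.shape[1]):
            m0 += XK1[n, c] * bK1[c]
        for c in range(XVND.shape[1]):
            m1 += XVND[n, c] * bVND[c]
        for c in range(XBPND.shape[1]):
            m2 += XBPND[n, c] * bBP[c]
        for c in range(Xk4.shape[1]):
            m3 += Xk4[n, c] * bk4[c]
        r[n, 0] = V[n, 0] - m0
        r[n, 1] = V[n, 1] - m1
        r[n, 2] = V[n, 2] - m2
        r[n, 3] = V[n, 3] - m3
        # forward solve M w = r_n
        for a in range(4):
            acc = r[n, a]
            for b_ in range(a):
                acc -= M[a, b_] * w[b_]
            w[a] = acc / M[a, a]
        lp += -0.5 * (w[0] ** 2 + w[1] ** 2 + w[2] ** 2 + w[3] ** 2)
        # backward solve M^T u = w  ->  Geta_n = Sigma^-1 r_n
        for a in range(3, -1, -1):
            acc = w[a]
            for b_ in range(a + 1, 4):
                acc -= M[b_, a] * Geta[n, b_]
            Geta[n, a] = acc / M[a, a]

    # ---- backprop: mean structure ----
    ga = grad[offs[0]:offs[0] + 4]
    gdK1 = grad[offs[1]:offs[2]]
    gdBP = grad[offs[2]:offs[3]]
    gbK1 = grad[offs[3]:offs[4]]
    gbVND = grad[offs[4]:offs[5]]
    gbBP = grad[offs[5]:offs[6]]
    gbk4 = grad[offs[6]:offs[7]]
    gz_subj = grad[offs[13]:offs[14]].reshape(J, 4)
    gz_reg = grad[offs[14]:offs[15]].reshape(K, 2)
    gls_subj = grad[offs[7]:offs[7] + 4]
    gls_reg = grad[offs[8]:offs[8] + 2]
    gls_tac = grad[offs[9]:offs[9] + 4]

    Tsub = np.zeros((J, 4))
    Treg = np.zeros((K, 2))
    for n in range(N):
        j = si[n]
        k = ri[n]
        for p in range(4):
            ga[p] += Geta[n, p]
            Tsub[j, p] += Geta[n, p]
        Treg[k, 0] += Geta[n, 1]
        Treg[k, 1] += Geta[n, 3]
        if k > 0:
            gdK1[k - 1] += Geta[n, 0]
            gdBP[k - 1] += Geta[n, 2]
        for c in range(XK1.shape[1]):
            gbK1[c] += XK1[n, c] * Geta[n, 0]
        for c in range(XVND.shape[1]):
            gbVND[c] += XVND[n, c] * Geta[n, 1]
        for c in range(XBPND.shape[1]):
            gbBP[c] += XBPND[n, c] * Geta[n, 2]
        for c in range(Xk4.shape[1]):
            gbk4[c] += Xk4[n, c] * Geta[n, 3]

    GLsub = np.zeros((4, 4))
    for j in range(J):
        for p in range(4):
            t = Tsub[j, p] * s_subj[p]
            gls_subj[p] += Tsub[j, p] * tau[j, p]
            for q in range(p + 1):
                gz_subj[j, q] += t * L_subj[p, q]
                GLsub[p, q] += t * z_subj[j, q]
    GLreg = np.zeros((2, 2))
    for k in range(K):
        for p in range(2):
            t = Treg[k, p] * s_reg[p]
            gls_reg[p] += Treg[k, p] * ups[k, p]
            for q in range(p + 1):
                gz_reg[k, q] += t * L_reg[p, q]
                GLreg[p, q] += t * z_reg[k, q]

    # ---- backprop: residual covariance ----
    # dlp/dSigma = 0.5 (Geta^T Geta - N Sigma^-1); grad_M = 2 G_Sigma M
    Sinv = np.zeros((4, 4))     # Sigma^-1 = M^-T M^-1 via solves with e_a
    for a in range(4):
        col = np.zeros(4)
        col[a] = 1.0
        # forward solve M v = e_a
        v = np.zeros(4)
        for i in range(4):
            acc = col[i]
            for b_ in range(i):
                acc -= M[i, b_] * v[b_]
            v[i] = acc / M[i, i]
        # backward solve M^T u = v
        u = np.zeros(4)
        for i in range(3, -1, -1):
            acc = v[i]
            for b_ in range(i + 1, 4):
                acc -= M[b_, i] * u[b_]
            u[i] = acc / M[i, i]
        for i in range(4):
            Sinv[i, a] = u[i]

    GS = np.zeros((4, 4))
    for a in range(4):
        for b_ in range(4):
            acc = 0.0
            for n in range(N):
                acc += Geta[n, a] * Geta[n, b_]
            GS[a, b_] = 0.5 * (acc - N * Sinv[a, b_])
    GM = np.zeros((4, 4))
    for a in range(4):
        for b_ in range(a + 1):
            acc = 0.0
            for c in range(4):
                acc += 2.0 * GS[a, c] * M[c, b_]
            GM[a, b_] = acc
    for p in range(4):
        for b_ in range(p + 1):
            gls_tac[p] += GM[p, b_] * M[p, b_]
    if multivariate:
        gy = grad[offs[12]:offs[12] + 6]
        for c in range(6):
            acc = 0.0
            for a in range(4):
                for b_ in range(a + 1):
                    acc += GM[a, b_] * s_tac[a] * J_tac[a, b_, c]
            gy[c] += acc
        gy = grad[offs[10]:offs[10] + 6]
        for c in range(6):
            acc = 0.0
            for a in range(4):
                for b_ in range(a + 1):
                    acc += GLsub[a, b_] * J_subj[a, b_, c]
            gy[c] += acc
        gy = grad[offs[11]:offs[11] + 1]
        acc = 0.0
        for a in range(2):
            for b_ in range(a + 1):
                acc += GLreg[a, b_] * J_reg[a, b_, 0]
        gy[0] += acc

    # ---- priors ----
    for i in range(offs[7]):
        rr = (x[i] - norm_loc[i]) / norm_scale[i]
        lp += -0.5 * rr * rr
        grad[i] += -rr / norm_scale[i]
    for i in range(10):
        ii = offs[7] + i
        uu = np.exp(2.0 * x[ii]) / (3.0 * sd_scales[i] ** 2)
        lp += -2.0 * np.log1p(uu) + x[ii]
        grad[ii] += 1.0 - 4.0 * uu / (1.0 + uu)
    if multivariate:
        zall = np.concatenate((zc_subj, zc_reg, zc_tac))
        for i in range(13):
            lp += lkj_b[i] * np.log1p(-zall[i] * zall[i])
            grad[offs[10] + i] += -2.0 * lkj_b[i] * zall[i]
    for i in range(offs[13], dim):
        lp += -0.5 * x[i] * x[i]
        grad[i] += -x[i]

    if not np.isfinite(lp):
        return -np.inf, np.zeros(dim)
    return lp, grad


@njit(cache=True)
def simba_trajectory(x0, p0, g0, eps, n_leap, inv_mass,
                     offs, J, K, N, multivariate, si, ri,
                     XK1, XVND, XBPND, Xk4, XvB, Xsig,
                     B, wstar, y, mask, cb, tmid, aifp, aif_idx,
                     norm_loc, norm_scale, sd_scales, lkj_b, fd_h):
    """Full leapfrog trajectory for the TAC model (one kernel call)."""
    x = x0.copy()
    p = p0.copy()
    g = g0.copy()
    lp = -np.inf
    for _ in range(n_leap):
        p += 0.5 * eps * g
        x += eps * inv_mass * p
        lp, g = simba_logp_grad(x, offs, J, K, N, multivariate, si, ri,
                                XK1, XVND, XBPND, Xk4, XvB, Xsig,
                                B, wstar, y, mask, cb, tmid, aifp, aif_idx,
                                norm_loc, norm_scale, sd_scales, lkj_b, fd_h)
        if not np.isfinite(lp):
            return x, p, -np.inf, g, False
        p += 0.5 * eps * g
    return x, p, lp, g, True


@njit(cache=True)
def values_trajectory(x0, p0, g0, eps, n_leap, inv_mass,
                      offs, J, K, N, multivariate, si, ri, V,
                      XK1, XVND, XBPND, Xk4,
                      norm_loc, norm_scale, sd_scales, lkj_b):
    """Full leapfrog trajectory for the fit-to-values model."""
    x = x0.copy()
    p = p0.copy()
    g = g0.copy()
    lp = -np.inf
    for _ in range(n_leap):
        p += 0.5 * eps * g
        x += eps * inv_mass * p
        lp, g = values_logp_grad(x, offs, J, K, N, multivariate, si, ri, V,
                                 XK1, XVND, XBPND, Xk4,
                                 norm_loc, norm_scale, sd_scales, lkj_b)
        if not np.isfinite(lp):
            return x, p, -np.inf, g, False
        p += 0.5 * eps * g
    return x, p, lp, g, True
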