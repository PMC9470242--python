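"""Log-posterior and gradient machinery for the hierarchical model.

Two target densities are defined over unconstrained parameter vectors:

* :class:`SimbaModel` -- the full model: Gaussian frame likelihood through
  the 2TC forward map, multivariate partial pooling of (log K1, log VND,
  log BPND, log k4) across subjects and TACs, of (log VND, log k4) across
  regions, univariate pooling for log vB and the log measurement error, a
  smooth-in-time component of the error SD, unpooled region dummies for K1
  and BPND, and arbitrary covariates per parameter.

* :class:`ValuesModel` -- the same multifactor mean structure fitted
  directly to per-TAC log parameter values, with the TAC-level multivariate
  normal acting as the residual distribution (no forward model).

Hierarchy deviations are non-centred (deviation = SD * L * z with z standard
normal).  Correlation matrices are parameterised by canonical partial
correlations through tanh, under which the LKJ(eta) density factorises into
independent scaled-Beta terms.  Gradients are analytic everywhere except (a)
the 2TC forward map, differentiated by batched forward differences in the
four nonlinear log parameters, and (b) the small cpc->Cholesky map and the
residual-covariance block of :class:`ValuesModel`, differentiated by central
differences at negligible cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from . import _forward, _mcore
from .params import PK_PARAMS

FD_H = 1e-6  # log-scale step for forward-map differentiation

# ---------------------------------------------------------------------------
# correlation-matrix parameterisation


@njit(cache=True)
def _cpc_to_chol(z: np.ndarray, d: int) -> np.ndarray:
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


def cpc_to_chol(z, d: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial corrs."""
    return _cpc_to_chol(np.asarray(z, dtype=float), d)






def lkj_cpc_exponents(d: int, eta: float) -> np.ndarray:
    """Beta shape b per cpc (row-major order); density term (1-z^2)^(b-1)."""
    return np.array([eta + (d - 2 - j) / 2.0 for i in range(1, d) for j in range(i)])








# ---------------------------------------------------------------------------
# layout


class Layout:
    """Named contiguous blocks of the unconstrained parameter vector."""

    def __init__(self):
        self.slices: dict[str, slice] = {}
        self.shapes: dict[str, tuple] = {}
        self.names: list[str] = []
        self._n = 0

    def add(self, name: str, shape, labels=None):
        shape = (shape,) if isinstance(shape, int) else tuple(shape)
        size = int(np.prod(shape))
        self.slices[name] = slice(self._n, self._n + size)
        self.shapes[name] = shape
        if labels is None:
            labels = [str(i) for i in range(size)] if size > 1 else [""]
        if size == 0:
            labels = []
        self.names.extend(f"{name}[{l}]" if l else name for l in labels)
        self._n += size

    @property
    def dim(self) -> int:
        return self._n

    def unpack(self, vec: np.ndarray) -> dict:
        return {k: vec[s].reshape(self.shapes[k]) for k, s in self.slices.items()}


def _pair_labels(names):
    return [f"{names[i]},{names[j]}" for i in range(1, len(names)) for j in range(i)]


# ---------------------------------------------------------------------------
# design container


@dataclass
class Design:
    """Everything the samplers need, assembled from a study."""

    y: np.ndarray                    # (F, N) observed activities (0 where missing)
    mask: np.ndarray                 # (F, N) 1.0 observed / 0.0 missing
    tmid: np.ndarray                 # (F,)
    cb: np.ndarray                   # (F, N) whole-blood frame means
    aif_rows: np.ndarray             # (S, 9)
    aif_idx: np.ndarray              # (N,)
    subj_idx: np.ndarray             # (N,)
    reg_idx: np.ndarray              # (N,)
    subjects: list
    regions: list
    X: dict                          # param -> (N, p) float arrays
    X_names: dict                    # param -> list of column names
    B: np.ndarray                    # (F, n_spline) smooth basis over frame time
    wstar: np.ndarray | None = None  # (F, N) fixed log-error offset
    tac_table: object = None         # per-TAC metadata DataFrame

    @property
    def n_subjects(self):
        return len(self.subjects)

    @property
    def n_regions(self):
        return len(self.regions)

    @property
    def n_tacs(self):
        return self.subj_idx.size

    @property
    def sigma_rows(self) -> int:
        """Row count of the per-frame error-model design."""
        return int(self.mask.sum())


def thinplate_basis(t: np.ndarray, n_basis: int = 8) -> np.ndarray:
    """Thin-plate-style smooth basis over time: a linear column plus the
    leading eigenvectors of the double-centred |t_i - t_j|^3 radial matrix.
    Columns are mean-centred and unit-scaled (the intercept lives elsewhere)."""
    t = np.asarray(t, dtype=float)
    F = t.size
    if n_basis > F:
        raise ValueError("more basis functions than time points")
    tn = (t - t.mean()) / t.std()
    E = np.abs(tn[:, None] - tn[None, :]) ** 3
    H = np.eye(F) - np.ones((F, F)) / F
    C = H @ E @ H
    w, V = np.linalg.eigh(C)
    order = np.argsort(-np.abs(w))
    cols = [tn]
    for idx in order[: n_basis - 1]:
        v = V[:, idx]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        cols.append(v)
    B = np.column_stack(cols)
    B -= B.mean(axis=0)
    sd = B.std(axis=0)
    sd[sd == 0] = 1.0
    return B / sd


# ---------------------------------------------------------------------------
# priors


@dataclass
class PriorConfig:
    """Weakly-informative defaults; see the methods note for rationale."""

    alpha_loc: dict = field(default_factory=lambda: {
        "K1": np.log(0.1), "VND": np.log(0.5), "BPND": np.log(2.0),
        "k4": np.log(0.03), "vB": np.log(0.05), "sigma": None})
    alpha_scale: dict = field(default_factory=lambda: {
        "K1": 0.3, "VND": 0.4, "BPND": 0.5, "k4": 0.4, "vB": 0.3, "sigma": 1.0})
    beta_scale: float = 0.3
    dummy_scale: float = 1.0
    sd_scale_subject: float = 0.4
    sd_scale_region: float = 0.2
    sd_scale_tac: float = 0.15
    sd_scale_vB: tuple = (0.3, 0.15)
    sd_scale_sigma: tuple = (0.3, 0.2)
    sd_scale_smooth: float = 0.5
    lkj_eta_subject: float = 1.0
    lkj_eta_region: float = 2.0
    lkj_eta_tac: float = 2.0

    def __post_init__(self):
        for k, v in self.alpha_scale.items():
            if v <= 0:
                raise ValueError(f"alpha scale for {k} must be positive")


# ---------------------------------------------------------------------------
# full model


class SimbaModel:
    """Unconstrained log-posterior of the full hierarchical TAC model."""

    def __init__(self, design: Design, priors: PriorConfig | None = None,
                 multivariate: bool = True):
        self.d = design
        self.priors = priors or PriorConfig()
        self.multivariate = multivariate
        d = design
        J, K, N = d.n_subjects, d.n_regions, d.n_tacs

        # aggregation matrices (subject / region sums over TACs)
        self.M_subj = np.zeros((J, N))
        self.M_subj[d.subj_idx, np.arange(N)] = 1.0
        self.M_reg = np.zeros((K, N))
        self.M_reg[d.reg_idx, np.arange(N)] = 1.0

        lay = Layout()
        lay.add("alpha", 6, ["K1", "VND", "BPND", "k4", "vB", "sigma"])
        lay.add("d_K1", K - 1, d.regions[1:])
        lay.add("d_BPND", K - 1, d.regions[1:])
        for p in ("K1", "VND", "BPND", "k4", "vB", "sigma"):
            cols = d.X_names.get(p, [])
            lay.add(f"beta_{p}", len(cols), cols)
        lay.add("log_sd_subject", 4, list(PK_PARAMS))
        lay.add("log_sd_region", 2, ["VND", "k4"])
        lay.add("log_sd_tac", 4, list(PK_PARAMS))
        lay.add("log_sd_vB", 2, ["subject", "region"])
        lay.add("log_sd_sigma", 2, ["subject", "region"])
        lay.add("log_sd_smooth", 1)
        nc = (6, 1, 6) if multivariate else (0, 0, 0)
        lay.add("corr_subject", nc[0], _pair_labels(PK_PARAMS))
        lay.add("corr_region", nc[1], ["VND,k4"])
        lay.add("corr_tac", nc[2], _pair_labels(PK_PARAMS))
        lay.add("z_subject", (J, 4), [f"{s},{p}" for s in d.subjects for p in PK_PARAMS])
        lay.add("z_region", (K, 2), [f"{r},{p}" for r in d.regions for p in ("VND", "k4")])
        lay.add("z_tac", (N, 4), [f"{n},{p}" for n in range(N) for p in PK_PARAMS])
        lay.add("z_vB_subject", J, d.subjects)
        lay.add("z_vB_region", K, d.regions)
        lay.add("z_sigma_subject", J, d.subjects)
        lay.add("z_sigma_region", K, d.regions)
        lay.add("gamma", d.B.shape[1])
        self.layout = lay

        self.b_subj = lkj_cpc_exponents(4, self.priors.lkj_eta_subject)
        self.b_reg = lkj_cpc_exponents(2, self.priors.lkj_eta_region)
        self.b_tac = lkj_cpc_exponents(4, self.priors.lkj_eta_tac)

        # data-scaled location for the error intercept
        mean_abs = float(np.sum(np.abs(d.y) * d.mask) / d.mask.sum())
        loc = self.priors.alpha_loc.get("sigma")
        self.asig_loc = float(np.log(0.1 * mean_abs)) if loc is None else float(loc)

        self.wstar = d.wstar if d.wstar is not None else np.zeros_like(d.y)

        # vectorised prior bookkeeping: [normal blocks | half-t log-SD blocks |
        # lkj cpc blocks | standard-normal tail]
        pr, sl = self.priors, lay.slices
        self._norm_slice = slice(0, sl["log_sd_subject"].start)
        loc_v = np.zeros(self._norm_slice.stop)
        scale_v = np.empty(self._norm_slice.stop)
        loc_v[sl["alpha"]] = [pr.alpha_loc[p] for p in ("K1", "VND", "BPND", "k4", "vB")] + [self.asig_loc]
        scale_v[sl["alpha"]] = [pr.alpha_scale[p] for p in ("K1", "VND", "BPND", "k4", "vB", "sigma")]
        scale_v[sl["d_K1"]] = pr.dummy_scale
        scale_v[sl["d_BPND"]] = pr.dummy_scale
        for p in ("K1", "VND", "BPND", "k4", "vB", "sigma"):
            if f"beta_{p}" in sl:
                scale_v[sl[f"beta_{p}"]] = pr.beta_scale
        self._norm_loc, self._norm_scale = loc_v, scale_v
        self._sd_slice = slice(sl["log_sd_subject"].start, sl["log_sd_smooth"].stop)
        self._sd_scales = np.concatenate([
            np.full(4, pr.sd_scale_subject), np.full(2, pr.sd_scale_region),
            np.full(4, pr.sd_scale_tac), np.asarray(pr.sd_scale_vB, dtype=float),
            np.asarray(pr.sd_scale_sigma, dtype=float), [pr.sd_scale_smooth]])
        self._lkj_b = np.concatenate([self.b_subj, self.b_reg, self.b_tac]) \
            if multivariate else np.zeros(13)

        # constant arrays for the jitted kernel
        order = ("alpha", "d_K1", "d_BPND", "beta_K1", "beta_VND", "beta_BPND",
                 "beta_k4", "beta_vB", "beta_sigma", "log_sd_subject",
                 "log_sd_region", "log_sd_tac", "log_sd_vB", "log_sd_sigma",
                 "log_sd_smooth", "corr_subject", "corr_region", "corr_tac",
                 "z_subject", "z_region", "z_tac", "z_vB_subject", "z_vB_region",
                 "z_sigma_subject", "z_sigma_region", "gamma")
        self._offs = np.array([sl[b].start for b in order] + [lay.dim], dtype=np.int64)
        self._si = np.ascontiguousarray(d.subj_idx, dtype=np.int64)
        self._ri = np.ascontiguousarray(d.reg_idx, dtype=np.int64)
        self._Xarr = tuple(
            np.ascontiguousarray(d.X.get(p, np.zeros((N, 0))), dtype=float)
            for p in ("K1", "VND", "BPND", "k4", "vB", "sigma"))

    @property
    def dim(self):
        return self.layout.dim

    @property
    def names(self):
        return self.layout.names

    def initial_point(self, rng) -> np.ndarray:
        x = np.zeros(self.dim)
        u = self.layout.unpack(x)
        pr = self.priors
        u["alpha"][:] = [pr.alpha_loc[p] for p in ("K1", "VND", "BPND", "k4", "vB")] + [self.asig_loc]
        u["alpha"] += 0.05 * rng.standard_normal(6)
        u["log_sd_subject"][:] = np.log(0.5 * pr.sd_scale_subject)
        u["log_sd_region"][:] = np.log(0.5 * pr.sd_scale_region)
        u["log_sd_tac"][:] = np.log(0.5 * pr.sd_scale_tac)
        u["log_sd_vB"][:] = np.log(0.5 * np.asarray(pr.sd_scale_vB))
        u["log_sd_sigma"][:] = np.log(0.5 * np.asarray(pr.sd_scale_sigma))
        u["log_sd_smooth"][:] = np.log(0.5 * pr.sd_scale_smooth)
        for k in ("z_subject", "z_region", "z_tac", "z_vB_subject", "z_vB_region",
                  "z_sigma_subject", "z_sigma_region", "gamma"):
            u[k][:] = 0.1 * rng.standard_normal(u[k].shape)
        return x

    def logp_grad(self, x: np.ndarray):
        """Joint log posterior and its gradient (delegates to the jitted core)."""
        d = self.d
        XK1, XVND, XBPND, Xk4, XvB, Xsig = self._Xarr
        return _mcore.simba_logp_grad(
            np.ascontiguousarray(x, dtype=float), self._offs,
            d.n_subjects, d.n_regions, d.n_tacs, self.multivariate,
            self._si, self._ri, XK1, XVND, XBPND, Xk4, XvB, Xsig,
            d.B, self.wstar, d.y, d.mask, d.cb, d.tmid, d.aif_rows,
            np.ascontiguousarray(d.aif_idx, dtype=np.int64),
            self._norm_loc, self._norm_scale, self._sd_scales, self._lkj_b, FD_H)

    def trajectory(self, x, p, g, eps, n_leap, inv_mass):
        """Fused jitted leapfrog trajectory (see :func:`_mcore.simba_trajectory`)."""
        d = self.d
        XK1, XVND, XBPND, Xk4, XvB, Xsig = self._Xarr
        return _mcore.simba_trajectory(
            x, p, g, eps, n_leap, inv_mass, self._offs,
            d.n_subjects, d.n_regions, d.n_tacs, self.multivariate,
            self._si, self._ri, XK1, XVND, XBPND, Xk4, XvB, Xsig,
            d.B, self.wstar, d.y, d.mask, d.cb, d.tmid, d.aif_rows,
            np.ascontiguousarray(d.aif_idx, dtype=np.int64),
            self._norm_loc, self._norm_scale, self._sd_scales, self._lkj_b, FD_H)


# ---------------------------------------------------------------------------
# fit-to-values model


class ValuesModel:
    """Multifactor hierarchical model fitted directly to log parameter values.

    The per-TAC 4-vector (log K1, log VND, log BPND, log k4) is the response;
    the TAC-level (multivariate) normal is the residual distribution, so
    there are no TAC-level latent parameters.
    """

    def __init__(self, V: np.ndarray, subj_idx, reg_idx, subjects, regions,
                 X: dict, X_names: dict, priors: PriorConfig | None = None,
                 multivariate: bool = True):
        self.V = np.ascontiguousarray(V, dtype=float)
        self.subj_idx = np.ascontiguousarray(subj_idx, dtype=np.int64)
        self.reg_idx = np.ascontiguousarray(reg_idx, dtype=np.int64)
        self.subjects, self.regions = list(subjects), list(regions)
        self.X, self.X_names = X, X_names
        self.priors = priors or PriorConfig()
        self.multivariate = multivariate
        J, K, N = len(subjects), len(regions), self.V.shape[0]

        lay = Layout()
        lay.add("alpha", 4, list(PK_PARAMS))
        lay.add("d_K1", K - 1, self.regions[1:])
        lay.add("d_BPND", K - 1, self.regions[1:])
        for p in PK_PARAMS:
            cols = X_names.get(p, [])
            lay.add(f"beta_{p}", len(cols), cols)
        lay.add("log_sd_subject", 4, list(PK_PARAMS))
        lay.add("log_sd_region", 2, ["VND", "k4"])
        lay.add("log_sd_tac", 4, list(PK_PARAMS))
        nc = (6, 1, 6) if multivariate else (0, 0, 0)
        lay.add("corr_subject", nc[0], _pair_labels(PK_PARAMS))
        lay.add("corr_region", nc[1], ["VND,k4"])
        lay.add("corr_tac", nc[2], _pair_labels(PK_PARAMS))
        lay.add("z_subject", (J, 4), [f"{s},{p}" for s in subjects for p in PK_PARAMS])
        lay.add("z_region", (K, 2), [f"{r},{p}" for r in regions for p in ("VND", "k4")])
        self.layout = lay
        self.b_subj = lkj_cpc_exponents(4, self.priors.lkj_eta_subject)
        self.b_reg = lkj_cpc_exponents(2, self.priors.lkj_eta_region)
        self.b_tac = lkj_cpc_exponents(4, self.priors.lkj_eta_tac)

        pr, sl = self.priors, lay.slices
        order = ("alpha", "d_K1", "d_BPND", "beta_K1", "beta_VND", "beta_BPND",
                 "beta_k4", "log_sd_subject", "log_sd_region", "log_sd_tac",
                 "corr_subject", "corr_region", "corr_tac", "z_subject", "z_region")
        self._offs = np.array([sl[b].start for b in order] + [lay.dim], dtype=np.int64)
        loc_v = np.zeros(sl["log_sd_subject"].start)
        scale_v = np.full(sl["log_sd_subject"].start, pr.beta_scale)
        loc_v[sl["alpha"]] = [pr.alpha_loc[p] for p in PK_PARAMS]
        scale_v[sl["alpha"]] = [pr.alpha_scale[p] for p in PK_PARAMS]
        scale_v[sl["d_K1"]] = pr.dummy_scale
        scale_v[sl["d_BPND"]] = pr.dummy_scale
        self._norm_loc, self._norm_scale = loc_v, scale_v
        # residual (TAC-level) SDs get a wider scale: they absorb the whole
        # TAC-to-TAC spread when fitting values directly
        self._sd_scales = np.concatenate([
            np.full(4, pr.sd_scale_subject), np.full(2, pr.sd_scale_region),
            np.full(4, 0.5)])
        self._lkj_b = np.concatenate([self.b_subj, self.b_reg, self.b_tac]) \
            if multivariate else np.zeros(13)
        self._Xarr = tuple(
            np.ascontiguousarray(X.get(p, np.zeros((N, 0))), dtype=float)
            for p in PK_PARAMS)

    @property
    def dim(self):
        return self.layout.dim

    @property
    def names(self):
        return self.layout.names

    def initial_point(self, rng) -> np.ndarray:
        x = np.zeros(self.dim)
        u = self.layout.unpack(x)
        pr = self.priors
        u["alpha"][:] = [pr.alpha_loc[p] for p in PK_PARAMS]
        u["alpha"] += 0.05 * rng.standard_normal(4)
        u["log_sd_subject"][:] = np.log(0.5 * pr.sd_scale_subject)
        u["log_sd_region"][:] = np.log(0.5 * pr.sd_scale_region)
        u["log_sd_tac"][:] = np.log(0.3)
        u["z_subject"][:] = 0.1 * rng.standard_normal(u["z_subject"].shape)
        u["z_region"][:] = 0.1 * rng.standard_normal(u["z_region"].shape)
        return x

    def logp_grad(self, x: np.ndarray):
        """Joint log posterior and gradient (delegates to the jitted core)."""
        XK1, XVND, XBPND, Xk4 = self._Xarr
        return _mcore.values_logp_grad(
            np.ascontiguousarray(x, dtype=float), self._offs,
            len(self.subjects), len(self.regions), self.V.shape[0],
            self.multivariate, self.subj_idx, self.reg_idx, self.V,
            XK1, XVND, XBPND, Xk4,
            self._norm_loc, self._norm_scale, self._sd_scales, self._lkj_b)

    def trajectory(self, x, p, g, eps, n_leap, inv_mass):
        """Fused jitted leapfrog trajectory for the values model."""
        XK1, XVND, XBPND, Xk4 = self._Xarr
        return _mcore.values_trajectory(
            x, p, g, eps, n_leap, inv_mass, self._offs,
            len(self.subjects), len(self.regions), self.V.shape[0],
            self.multivariate, self.subj_idx, self.reg_idx, self.V,
            XK1, XVND, XBPND, Xk4,
            self._norm_loc, self._norm_scale, self._sd_scales, self._lkj_b)
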