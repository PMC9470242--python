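"""Hierarchical multifactor Bayesian model for PET TAC data.

One joint model is fitted to every TAC of every subject: log-scale
pharmacokinetic parameters get a global intercept, covariate effects,
unpooled region dummies for K1 and BPND, and partially pooled deviations per
subject, per region (VND, k4, vB, sigma only) and per TAC (not vB / sigma),
with multivariate normal pooling and LKJ priors on the correlation matrices.
The frame likelihood is Gaussian with a log-linear SD model including a
smooth function of frame time.  Sampling is adaptive HMC with a
convergence/reseed-retry rule based on Rhat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _forward
from ._hmc import hmc_sample
from ._model import (Design, PriorConfig, SimbaModel, ValuesModel, cpc_to_chol,
                     thinplate_basis)
from .params import PK_PARAMS

__all__ = [
    "CovariateSpec", "PriorConfig", "SamplerConfig", "FitResult",
    "HierarchyDeviations", "build_design", "fit_simba", "fit_values",
    "check_convergence", "nls_parameter_count", "phi_vb_parameter_count",
    "posterior_correlations", "posterior_hierarchy",
]


@dataclass
class CovariateSpec:
    """Covariate columns per model parameter (region dummies are implicit)."""

    covariates: dict = field(default_factory=lambda: {"BPND": ["group"]})

    def columns_for(self, param: str) -> list:
        return list(self.covariates.get(param, []))

    def all_columns(self) -> set:
        return {c for cols in self.covariates.values() for c in cols}


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    max_retries: int = 3
    target_accept: float = 0.8
    max_leapfrog: int = 24

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for Rhat")
        if self.warmup < 1 or self.samples < 1:
            raise ValueError("warmup and samples must be >= 1")

    @classmethod
    def sweep(cls, seed: int = 0) -> "SamplerConfig":
        """Short-chain settings used for simulation sweeps."""
        return cls(chains=2, warmup=500, samples=500, seed=seed, max_leapfrog=128)


@dataclass
class HierarchyDeviations:
    """Posterior-mean deviations at each pooling level."""

    tau: np.ndarray          # (J, 4) subject deviations over PK_PARAMS
    upsilon: np.ndarray      # (K, 2) region deviations over (VND, k4)
    phi: np.ndarray | None   # (N, 4) TAC deviations (None for values model)
    tau_vB: np.ndarray | None
    upsilon_vB: np.ndarray | None
    tau_sigma: np.ndarray | None
    upsilon_sigma: np.ndarray | None


@dataclass
class FitResult:
    """Posterior draws with diagnostics."""

    draws: np.ndarray        # (chains, draws, dim)
    names: list
    rhat: np.ndarray
    converged: bool
    divergences: int
    attempts: int
    seeds: list
    accept_rate: float
    multivariate: bool

    def get(self, name: str) -> np.ndarray:
        """Pooled draws (all chains) of one named parameter."""
        idx = self.names.index(name)
        return self.draws[:, :, idx].reshape(-1)

    def names_matching(self, prefix: str) -> list:
        return [n for n in self.names if n.startswith(prefix)]

    def summary(self, prefix: str = "", level: float = 0.89) -> pd.DataFrame:
        rows = []
        q = [(1 - level) / 2, 1 - (1 - level) / 2]
        for i, n in enumerate(self.names):
            if prefix and not n.startswith(prefix):
                continue
            d = self.draws[:, :, i].reshape(-1)
            lo, hi = np.quantile(d, q)
            rows.append({"parameter": n, "mean": d.mean(), "sd": d.std(ddof=1),
                         "median": np.median(d), "lower": lo, "upper": hi,
                         "rhat": self.rhat[i]})
        return pd.DataFrame(rows)


def _code_covariates(table: pd.DataFrame, cols: list) -> tuple[np.ndarray, list]:
    """Treatment-code categoricals / centre continuous columns; rows = table rows."""
    mats, names = [], []
    for c in cols:
        if c not in table.columns:
            raise ValueError(f"covariate column {c!r} not found")
        v = table[c]
        if v.isna().any():
            bad = table.loc[v.isna(), "subject"].tolist()
            raise ValueError(f"missing values in covariate {c!r} for subjects {bad}")
        if v.dtype.kind in "OUSb" or v.nunique() == 2:
            levels = sorted(v.unique())
            for lev in levels[1:]:
                mats.append((v == lev).to_numpy(float))
                names.append(c if len(levels) == 2 else f"{c}[{lev}]")
        else:
            x = v.to_numpy(float)
            mats.append(x - x.mean())
            names.append(c)
    if not mats:
        return np.empty((len(table), 0)), []
    return np.column_stack(mats), names


def build_design(study, spec: CovariateSpec | None = None,
                 wstar_weights=None, n_spline: int = 8) -> Design:
    """Assemble design matrices, index maps and data arrays from a study.

    Region dummies (reference = first region in sorted order) are added for
    K1 and BPND; requested covariates are treatment-coded (categorical) or
    centred (continuous).  Parameter-level matrices have one row per TAC;
    the error model adds a smooth basis over frame time (one row per frame).
    """
    spec = spec or CovariateSpec()
    missing_cols = spec.all_columns() - set(study.covariates.columns)
    if missing_cols:
        raise ValueError(f"covariate columns not in study: {sorted(missing_cols)}")

    subjects, regions = study.subjects, study.regions
    sched = study.schedule
    F = sched.n_frames
    s_pos = {s: i for i, s in enumerate(subjects)}
    r_pos = {r: i for i, r in enumerate(regions)}

    pairs = sorted({(s, r) for s, r in
                    zip(study.tacs["subject"].astype(str), study.tacs["region"].astype(str))})
    N = len(pairs)
    subj_idx = np.array([s_pos[s] for s, _ in pairs], dtype=np.int64)
    reg_idx = np.array([r_pos[r] for _, r in pairs], dtype=np.int64)

    key = {(round(a, 6), round(b, 6)): i for i, (a, b) in enumerate(zip(sched.start, sched.end))}
    y = np.zeros((F, N))
    mask = np.zeros((F, N))
    tac_pos = {p: n for n, p in enumerate(pairs)}
    for row in study.tacs.itertuples(index=False):
        n = tac_pos[(str(row.subject), str(row.region))]
        i = key[(round(row.frame_start, 6), round(row.frame_end, 6))]
        y[i, n] = row.value
        mask[i, n] = 1.0

    aif_rows = np.stack([_forward.aif_row(study.aifs[s]) for s in subjects]) \
        if study.aifs else None
    if aif_rows is None:
        raise ValueError("design requires per-subject AIF parameters")
    aif_idx = subj_idx.copy()
    cb = np.stack([study.subject_wb_means(s) for s in subjects], axis=1)[:, subj_idx]

    cov = study.covariates.copy()
    cov["subject"] = cov["subject"].astype(str)
    cov = cov.set_index("subject").loc[[s for s, _ in pairs]].reset_index()
    X, X_names = {}, {}
    for p in ("K1", "VND", "BPND", "k4", "vB", "sigma"):
        cols = spec.columns_for(p)
        if cols:
            X[p], X_names[p] = _code_covariates(cov, cols)

    B = thinplate_basis(sched.midpoint, n_spline)
    wstar = None
    if wstar_weights is not None:
        lw = -0.5 * np.log(np.asarray(wstar_weights.w, dtype=float))
        wstar = np.repeat((lw - lw.mean())[:, None], N, axis=1)

    tac_table = pd.DataFrame({"subject": [s for s, _ in pairs],
                              "region": [r for _, r in pairs]})
    return Design(y=y, mask=mask, tmid=sched.midpoint, cb=cb, aif_rows=aif_rows,
                  aif_idx=aif_idx, subj_idx=subj_idx, reg_idx=reg_idx,
                  subjects=subjects, regions=regions, X=X, X_names=X_names,
                  B=B, wstar=wstar, tac_table=tac_table)


def _compute_rhat(draws: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        ds = az.convert_to_dataset(draws)
        return np.asarray(az.rhat(ds)["x"].values, dtype=float)


def _warm_start(model, seed: int) -> np.ndarray:
    """Posterior ascent to a good starting basin before sampling.

    Bounded L-BFGS on the joint log posterior with the hierarchy log-SD
    coordinates frozen at their initial values -- optimising those too would
    collapse the funnels to zero variance.  This removes the long low-density
    plateau that short warmups cannot cross.
    """
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    x0 = model.initial_point(rng)
    lb = np.full(x0.size, -np.inf)
    ub = np.full(x0.size, np.inf)
    for name, sl in model.layout.slices.items():
        if name.startswith("log_sd"):
            lb[sl] = x0[sl]
            ub[sl] = x0[sl]

    def fun(x):
        lp, g = model.logp_grad(x)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(x)
        return -lp, -g

    try:
        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       bounds=list(zip(lb, ub)), options={"maxiter": 200})
        if np.isfinite(res.fun):
            return res.x
    except Exception:
        pass
    return x0


def _run_chains(model, sampler: SamplerConfig, seed: int):
    warm = _warm_start(model, seed)
    chains = []
    infos = []
    for c in range(sampler.chains):
        rng = np.random.default_rng(seed + 17 * c)
        x0 = warm.copy()
        x0 += 0.02 * rng.standard_normal(x0.size)
        for name, sl in model.layout.slices.items():
            if name.startswith("z_"):
                x0[sl] += 0.1 * rng.standard_normal(sl.stop - sl.start)
        draws, info = hmc_sample(model.logp_grad, x0, sampler.warmup, sampler.samples,
                                 rng, target_accept=sampler.target_accept,
                                 max_leapfrog=sampler.max_leapfrog,
                                 trajectory=getattr(model, "trajectory", None))
        chains.append(draws)
        infos.append(info)
    return np.stack(chains), infos


def _rhat_ok(rhat: np.ndarray) -> bool:
    if np.any(~np.isfinite(rhat)):
        return False
    return bool(np.max(rhat) <= 1.25 and np.mean(rhat > 1.05) <= 0.02)


def _fit(model, sampler: SamplerConfig) -> FitResult:
    seeds = []
    best = None
    for attempt in range(sampler.max_retries + 1):
        seed = sampler.seed + 100_003 * attempt
        seeds.append(seed)
        draws, infos = _run_chains(model, sampler, seed)
        rhat = _compute_rhat(draws)
        ok = _rhat_ok(rhat)
        res = FitResult(draws=draws, names=list(model.names), rhat=rhat, converged=ok,
                        divergences=int(sum(i["divergences"] for i in infos)),
                        attempts=attempt + 1, seeds=list(seeds),
                        accept_rate=float(np.mean([i["accept_rate"] for i in infos])),
                        multivariate=model.multivariate)
        if ok:
            return res
        if best is None or np.max(rhat) < np.max(best.rhat):
            best = res
    # exhausted: report the best attempt but the full retry history
    best.attempts = sampler.max_retries + 1
    best.seeds = list(seeds)
    return best


def fit_simba(design: Design, priors: PriorConfig | None = None,
              sampler: SamplerConfig | None = None, multivariate: bool = True) -> FitResult:
    """Sample the joint posterior of the full hierarchical TAC model.

    On non-convergence (Rhat rule of :func:`check_convergence`) the model is
    refitted with a fresh random seed, up to ``sampler.max_retries`` times;
    data and priors are never altered between attempts.
    """
    model = SimbaModel(design, priors=priors, multivariate=multivariate)
    return _fit(model, sampler or SamplerConfig())


def fit_values(table: pd.DataFrame, spec: CovariateSpec | None = None,
               priors: PriorConfig | None = None, sampler: SamplerConfig | None = None,
               multivariate: bool = True) -> FitResult:
    """Fit the multifactor hierarchy directly to per-TAC log parameter values.

    ``table`` needs columns subject, region, log_K1, log_VND, log_BPND,
    log_k4 plus any covariates (e.g. group).  The TAC-level distribution is
    the residual, so this is the 'analysis of true values' variant.
    """
    spec = spec or CovariateSpec()
    table = table.copy()
    table["subject"] = table["subject"].astype(str)
    table["region"] = table["region"].astype(str)
    subjects = sorted(table["subject"].unique())
    regions = sorted(table["region"].unique())
    s_pos = {s: i for i, s in enumerate(subjects)}
    r_pos = {r: i for i, r in enumerate(regions)}
    table = table.sort_values(["subject", "region"]).reset_index(drop=True)
    V = table[[f"log_{p}" for p in PK_PARAMS]].to_numpy(float)
    subj_idx = table["subject"].map(s_pos).to_numpy()
    reg_idx = table["region"].map(r_pos).to_numpy()
    X, X_names = {}, {}
    for p in PK_PARAMS:
        cols = spec.columns_for(p)
        if cols:
            X[p], X_names[p] = _code_covariates(table, cols)
    model = ValuesModel(V, subj_idx, reg_idx, subjects, regions, X, X_names,
                        priors=priors, multivariate=multivariate)
    return _fit(model, sampler or SamplerConfig())


def check_convergence(fit: FitResult) -> bool:
    """Converged iff max Rhat <= 1.25 and at most 2% of parameters exceed 1.05."""
    if fit.rhat is None or np.any(~np.isfinite(fit.rhat)):
        raise ValueError("Rhat is missing or undefined for some parameters")
    return _rhat_ok(fit.rhat)


def posterior_hierarchy(fit: FitResult, design: Design, thin: int = 5) -> HierarchyDeviations:
    """Posterior-mean deviations at each pooling level.

    Deviations are reconstructed draw by draw (deviation = SD * L * z) on a
    thinned subset, then averaged; levels absent from the model are None.
    """
    c, d, k = fit.draws.shape
    flat = fit.draws.reshape(c * d, k)[::thin]
    name_idx = {n: i for i, n in enumerate(fit.names)}

    def cols(prefix):
        idx = [i for n, i in name_idx.items() if n.startswith(prefix)]
        return flat[:, idx]

    def block_dev(z_prefix, sd_prefix, corr_prefix, n_units, dim):
        z = cols(z_prefix).reshape(flat.shape[0], n_units, dim)
        s = np.exp(cols(sd_prefix))
        out = np.zeros((n_units, dim))
        for t in range(flat.shape[0]):
            L = np.eye(dim)
            if fit.multivariate:
                y = flat[t, [name_idx[n] for n in fit.names if n.startswith(corr_prefix)]]
                L = cpc_to_chol(np.tanh(y), dim)
            out += (z[t] @ L.T) * s[t]
        return out / flat.shape[0]

    J, K, N = design.n_subjects, design.n_regions, design.n_tacs
    tau = block_dev("z_subject[", "log_sd_subject[", "corr_subject[", J, 4)
    ups = block_dev("z_region[", "log_sd_region[", "corr_region[", K, 2)
    phi = block_dev("z_tac[", "log_sd_tac[", "corr_tac[", N, 4)

    def univ(z_prefix, sd_name):
        z = cols(z_prefix)
        s = np.exp(flat[:, name_idx[sd_name]])
        return (z * s[:, None]).mean(axis=0)

    return HierarchyDeviations(
        tau=tau, upsilon=ups, phi=phi,
        tau_vB=univ("z_vB_subject[", "log_sd_vB[subject]"),
        upsilon_vB=univ("z_vB_region[", "log_sd_vB[region]"),
        tau_sigma=univ("z_sigma_subject[", "log_sd_sigma[subject]"),
        upsilon_sigma=univ("z_sigma_region[", "log_sd_sigma[region]"))


def posterior_correlations(fit: FitResult, block: str = "tac") -> np.ndarray:
    """Per-draw correlation matrices (n_draws, d, d) for one pooling block."""
    if not fit.multivariate:
        raise ValueError("univariate fit has no correlation parameters")
    d = 2 if block == "region" else 4
    names = fit.names_matching(f"corr_{block}[")
    cols = np.stack([fit.get(n) for n in names], axis=1)
    out = np.empty((cols.shape[0], d, d))
    for i in range(cols.shape[0]):
        L = cpc_to_chol(np.tanh(cols[i]), d)
        out[i] = L @ L.T
    return out


def nls_parameter_count(n_subjects: int, n_regions: int, per_tac: int = 5) -> int:
    """Parameters estimated by per-TAC NLS: 5 per TAC."""
    return per_tac * n_subjects * n_regions


def phi_vb_parameter_count(n_subjects: int, n_regions: int) -> int:
    """TAC-level vB deviations omitted from the hierarchical model (one per TAC)."""
    return n_subjects * n_regions
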