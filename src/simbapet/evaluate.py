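"""Statistical inference and simulation-harness metrics.

Covers the decision rules and summaries used in the power evaluation:
equal-tailed credible intervals with directional probability, the
CrI-excludes-zero decision, the frequentist comparators (per-region Welch
t-tests and a random-intercept LME across regions), logspline power
estimation from credible-interval bounds across simulations with bootstrap
confidence intervals, recovery metrics (RMSE, Pearson r), bias/SD summaries,
and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize

__all__ = [
    "IntervalEstimate", "PowerEstimate", "RecoveryMetrics",
    "posterior_interval", "decide_group_difference", "comparator_tests",
    "logspline_exceedance", "power_logspline", "recovery_metrics",
    "bias_sd_summary", "cohens_d", "prob_estimate_above_truth",
]


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    pd: float  # directional probability in [0.5, 1]

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("interval must contain the point estimate")
        if not (0.5 - 1e-9 <= self.pd <= 1.0 + 1e-9):
            raise ValueError("Pd must lie in [0.5, 1]")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_lower: float
    ci_upper: float
    method: str          # "logspline" or "empirical"
    n_simulations: int

    def __post_init__(self):
        if not (self.ci_lower - 1e-9 <= self.power <= self.ci_upper + 1e-9):
            raise ValueError("bootstrap CI must contain the point estimate")


@dataclass(frozen=True)
class RecoveryMetrics:
    rmse: float
    pearson_r: float | None


def posterior_interval(draws, level: float = 0.89) -> IntervalEstimate:
    """Equal-tailed credible interval with directional probability.

    Pd is the share of draws on the side of zero indicated by the posterior
    median (hence always >= 0.5).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("at least 100 posterior draws are required")
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
    med = float(np.median(draws))
    p_pos = float(np.mean(draws > 0))
    p_neg = float(np.mean(draws < 0))
    return IntervalEstimate(point=med, lower=float(lo), upper=float(hi),
                            level=level, pd=max(p_pos, p_neg))


def decide_group_difference(interval: IntervalEstimate) -> int:
    """+1 / -1 if the interval excludes zero from below/above, else 0."""
    if interval.lower > 0:
        return 1
    if interval.upper < 0:
        return -1
    return 0


def comparator_tests(outcomes: pd.DataFrame, value_col: str = "log_BPND",
                     alpha: float = 0.05) -> dict:
    """Frequentist comparators on per-subject-per-region log outcomes.

    * Welch's t-test per region (two-sided, no multiplicity correction).
    * LME across regions: fixed effects for region and group, random
      intercept per subject; the group p-value uses a t reference with
      n_subjects - 2 df (the Satterthwaite df in this balanced design).

    ``outcomes`` needs columns subject, region, group, and ``value_col``.
    """
    for g, gdf in outcomes.groupby("group"):
        if gdf["subject"].nunique() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    glabels = sorted(outcomes["group"].unique())
    if len(glabels) != 2:
        raise ValueError("exactly two groups are required")

    region_tests = {}
    for reg, gdf in outcomes.groupby("region"):
        a = gdf.loc[gdf["group"] == glabels[0], value_col].to_numpy(float)
        b = gdf.loc[gdf["group"] == glabels[1], value_col].to_numpy(float)
        if np.var(a) + np.var(b) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(b, a, equal_var=False)
        region_tests[reg] = {"t": float(t), "p": float(p), "reject": bool(p < alpha)}

    import statsmodels.formula.api as smf

    df = outcomes.copy()
    df["grp"] = (df["group"] == glabels[1]).astype(float)
    est = se = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(f"{value_col} ~ C(region) + grp", df, groups=df["subject"])
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                fit = md.fit(reml=True, method=method)
                if np.isfinite(fit.params["grp"]) and np.isfinite(fit.bse["grp"]):
                    est = float(fit.params["grp"])
                    se = float(fit.bse["grp"])
                    break
            except Exception:
                continue
    if est is None:
        # balanced-design equivalent: pooled two-sample comparison of
        # subject-mean outcomes (identical group inference to the LME)
        sm_means = df.groupby(["subject", "grp"])[value_col].mean().reset_index()
        a = sm_means.loc[sm_means["grp"] == 0, value_col].to_numpy(float)
        b = sm_means.loc[sm_means["grp"] == 1, value_col].to_numpy(float)
        sp2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) \
            / (a.size + b.size - 2)
        est = float(b.mean() - a.mean())
        se = float(np.sqrt(sp2 * (1 / a.size + 1 / b.size)))
    dof = df["subject"].nunique() - 2
    tstat = est / se
    p_lme = float(2 * stats.t.sf(abs(tstat), dof))
    return {
        "t_tests": region_tests,
        "t_reject_any": any(v["reject"] for v in region_tests.values()),
        "t_reject_rate": float(np.mean([v["reject"] for v in region_tests.values()])),
        "lme": {"estimate": est, "se": se, "t": float(tstat), "df": dof,
                "p": p_lme, "reject": bool(p_lme < alpha)},
    }


def _fit_logspline(x: np.ndarray, n_basis: int):
    """ML log-density spline: log f = B(x) c - log Z, ridge-stabilised."""
    lo = x.min() - 2.5 * (x.std() + 1e-12)
    hi = x.max() + 2.5 * (x.std() + 1e-12)
    grid = np.linspace(lo, hi, 256)
    k = 3
    inner = np.linspace(lo, hi, n_basis - k + 1)
    knots = np.concatenate([[lo] * k, inner, [hi] * k])
    design = BSpline.design_matrix(np.clip(x, lo, hi), knots, k).toarray()
    dgrid = BSpline.design_matrix(grid, knots, k).toarray()
    dx = grid[1] - grid[0]

    def nll(c):
        u = dgrid @ c
        m = u.max()
        logZ = m + np.log(np.sum(np.exp(u - m)) * dx)
        return -(design @ c).sum() + x.size * logZ + 1e-3 * c @ c

    res = minimize(nll, np.zeros(dgrid.shape[1]), method="L-BFGS-B")
    u = dgrid @ res.x
    m = u.max()
    dens = np.exp(u - m)
    dens /= np.sum(dens) * dx
    nparam = dgrid.shape[1]
    aic = 2 * (res.fun - 1e-3 * res.x @ res.x) + 2 * nparam
    return grid, dens, aic


def logspline_exceedance(x, threshold: float = 0.0, side: str = "above") -> float:
    """P(X > threshold) (or <) under an ML logspline density fitted to x.

    The number of basis functions is chosen by AIC among a small candidate
    set; degenerate samples fall back to the empirical proportion.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) < 1e-12:
        warnings.warn("degenerate sample; using empirical proportion")
        p = float(np.mean(x > threshold))
        return p if side == "above" else 1.0 - p
    best = None
    for nb in (4, 5, 6, 8):
        if nb >= x.size:
            continue
        try:
            grid, dens, aic = _fit_logspline(x, nb)
        except Exception:
            continue
        if best is None or aic < best[2]:
            best = (grid, dens, aic)
    if best is None:
        p = float(np.mean(x > threshold))
        return p if side == "above" else 1.0 - p
    grid, dens, _ = best
    dx = grid[1] - grid[0]
    cdf = np.cumsum(dens) * dx
    p_below = float(np.interp(threshold, grid, cdf, left=0.0, right=1.0))
    return 1.0 - p_below if side == "above" else p_below


def power_logspline(lower_bounds, upper_bounds, B: int = 1000, seed: int = 0,
                    method: str = "logspline") -> PowerEstimate:
    """Power from 95% CrI bounds across simulations.

    power = P(lower > 0) + P(upper < 0) under logspline densities fitted to
    the lower and upper bounds respectively; the CI is a percentile bootstrap
    over simulations (B resamples).
    """
    lower = np.asarray(lower_bounds, dtype=float)
    upper = np.asarray(upper_bounds, dtype=float)
    if lower.size < 20:
        raise ValueError("at least 20 simulations are required")
    if lower.size != upper.size:
        raise ValueError("lower and upper bounds must pair up")

    def point(lo, up):
        if method == "empirical":
            return float(np.mean(lo > 0) + np.mean(up < 0))
        return min(1.0, logspline_exceedance(lo, 0.0, "above")
                   + logspline_exceedance(up, 0.0, "below"))

    est = point(lower, upper)
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, lower.size, lower.size)
        boot[b] = point(lower[idx], upper[idx])
    lo_ci, hi_ci = np.quantile(boot, [0.025, 0.975])
    lo_ci, hi_ci = min(lo_ci, est), max(hi_ci, est)
    return PowerEstimate(power=est, ci_lower=float(lo_ci), ci_upper=float(hi_ci),
                         method=method, n_simulations=int(lower.size))


def recovery_metrics(true_values, estimates) -> RecoveryMetrics:
    """RMSE and Pearson r between paired true and estimated values."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape or t.size < 3:
        raise ValueError("paired inputs of equal length >= 3 required")
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))
    if np.std(t) == 0 or np.std(e) == 0:
        return RecoveryMetrics(rmse=rmse, pearson_r=None)
    return RecoveryMetrics(rmse=rmse, pearson_r=float(stats.pearsonr(t, e)[0]))


def bias_sd_summary(estimates, true_effect: float, reported_ses=None) -> dict:
    """Bias, between-simulation SD, and mean reported SE of effect estimates."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("at least 2 simulations are required")
    out = {"bias": float(np.mean(est) - true_effect),
           "sd": float(np.std(est, ddof=1)),
           "mean_se": None}
    if reported_ses is not None:
        out["mean_se"] = float(np.mean(np.asarray(reported_ses, dtype=float)))
    return out


def prob_estimate_above_truth(bias: float, sd: float) -> float:
    """Normal-approximation P(estimate > truth) given bias and SD of estimates."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(stats.norm.sf(-bias / sd))


def cohens_d(group1_values, group2_values) -> float | None:
    """(mean2 - mean1) / pooled SD; None when the pooled SD is zero."""
    a = np.asarray(group1_values, dtype=float)
    b = np.asarray(group2_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 subjects")
    sp2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        return None
    return float((b.mean() - a.mean()) / np.sqrt(sp2))
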