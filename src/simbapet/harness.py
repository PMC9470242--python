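"""Replicated-simulation harnesses for power / false-positive evaluation.

These wrap the generator, the NLS baseline, the hierarchical model and the
decision rules into study-level sweeps.  The "smoke" conditions are the
package's scaled-down evaluation settings: 3 regions, a 12-frame schedule,
small groups and short chains, chosen so that method comparisons run on a
single CPU while preserving the structure of the full design (the methods
note discusses what does and does not transfer).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import IntervalEstimate, comparator_tests, decide_group_difference, posterior_interval
from .nls import fit_study_nls
from .params import PopulationParameters, default_population
from .simba import CovariateSpec, SamplerConfig, build_design, fit_simba
from .simulate import SimulationConfig, sample_truth, simulate_study, smoke_schedule

__all__ = [
    "SMOKE_REGIONS", "smoke_config", "power_population",
    "group_effect_interval", "simba_replicates", "comparator_rates_from_values",
    "comparator_null_rates", "method_comparison",
]

SMOKE_REGIONS = ("DLPFC", "ACC", "Hippocampus")


def smoke_config(n_per_group: int = 4, effect: float = 0.0, seed: int = 0,
                 error_scale: float = 0.10, correlations_on: bool = True,
                 regions: tuple = SMOKE_REGIONS) -> SimulationConfig:
    """Scaled-down simulation condition (3 regions, 12 frames)."""
    return SimulationConfig(n_per_group=n_per_group, regions=regions,
                            schedule=smoke_schedule(), effect_log_bpnd=effect,
                            error_scale=error_scale, correlations_on=correlations_on,
                            seed=seed)


def power_population(bpnd_subject_sd: float = 0.12) -> PopulationParameters:
    """Population for the scaled-down power-ordering condition.

    With few replicates and small groups, method powers are only separable
    when each method has mid-range power; the between-subject SD of log BPND
    is reduced (default 0.12, i.e. d ~ 1.5 at a 20% effect) for that purpose
    while every other component stays at its default.
    """
    pop = default_population()
    pop.sd_subject = pop.sd_subject.copy()
    pop.sd_subject[2] = bpnd_subject_sd
    return pop


def group_effect_interval(fit, level: float = 0.95) -> IntervalEstimate:
    """Posterior interval of the group difference in log BPND."""
    return posterior_interval(fit.get("beta_BPND[group]"), level=level)


def simba_replicates(n_reps: int, base_seed: int, effect: float,
                     pop: PopulationParameters | None = None,
                     n_per_group: int = 4, sampler: SamplerConfig | None = None,
                     error_scale: float = 0.10, correlations_on: bool = True,
                     multivariate: bool = True, level: float = 0.95) -> pd.DataFrame:
    """Fit the hierarchical model to replicate smoke studies.

    Returns one row per replicate with the group-effect estimate, the
    ``level`` CrI, the exclusion decision and convergence diagnostics.
    """
    pop = pop or default_population()
    rows = []
    for rep in range(n_reps):
        seed = base_seed + 1000 * rep
        cfg = smoke_config(n_per_group=n_per_group, effect=effect, seed=seed,
                           error_scale=error_scale, correlations_on=correlations_on)
        study = simulate_study(cfg, pop)
        design = build_design(study, CovariateSpec({"BPND": ["group"]}))
        smp = sampler or SamplerConfig.sweep()
        smp = SamplerConfig(chains=smp.chains, warmup=smp.warmup, samples=smp.samples,
                            seed=seed + 7, max_retries=smp.max_retries,
                            target_accept=smp.target_accept, max_leapfrog=smp.max_leapfrog)
        fit = fit_simba(design, sampler=smp, multivariate=multivariate)
        ci = group_effect_interval(fit, level=level)
        rows.append({"rep": rep, "estimate": ci.point, "lower": ci.lower,
                     "upper": ci.upper, "pd": ci.pd,
                     "se": float(np.std(fit.get("beta_BPND[group]"), ddof=1)),
                     "excludes_zero": decide_group_difference(ci) != 0,
                     "converged": fit.converged, "attempts": fit.attempts,
                     "max_rhat": float(np.max(fit.rhat))})
    return pd.DataFrame(rows)


def _values_table(cfg: SimulationConfig, pop) -> pd.DataFrame:
    return sample_truth(cfg, pop).params


def comparator_rates_from_values(n_reps: int, base_seed: int, effect: float,
                                 pop: PopulationParameters | None = None,
                                 n_per_group: int = 20,
                                 regions: tuple = SMOKE_REGIONS) -> pd.DataFrame:
    """t-test / LME decisions on true simulated log BPND values (no TACs)."""
    pop = pop or default_population()
    rows = []
    for rep in range(n_reps):
        cfg = SimulationConfig(n_per_group=n_per_group, regions=regions,
                               schedule=smoke_schedule(), effect_log_bpnd=effect,
                               seed=base_seed + 1000 * rep)
        t = _values_table(cfg, pop)
        res = comparator_tests(t, value_col="log_BPND")
        rows.append({"rep": rep, "t_reject_rate": res["t_reject_rate"],
                     "t_reject_any": res["t_reject_any"],
                     "lme_reject": res["lme"]["reject"],
                     "lme_estimate": res["lme"]["estimate"],
                     "lme_se": res["lme"]["se"]})
    return pd.DataFrame(rows)


def comparator_null_rates(n_reps: int = 200, n_per_group: int = 20, base_seed: int = 0,
                          pop: PopulationParameters | None = None,
                          regions: tuple = SMOKE_REGIONS) -> dict:
    """False-positive rates of the comparators under the null."""
    df = comparator_rates_from_values(n_reps, base_seed, effect=0.0, pop=pop,
                                      n_per_group=n_per_group, regions=regions)
    return {"t_rate": float(df["t_reject_rate"].mean()),
            "lme_rate": float(df["lme_reject"].mean()),
            "n_reps": n_reps}


POWER_REGIONS = ("DLPFC", "MPFC", "ACC", "Hippocampus", "Insula")


def method_comparison(n_reps: int, base_seed: int, effect: float,
                      pop: PopulationParameters | None = None,
                      n_per_group: int = 4, sampler: SamplerConfig | None = None,
                      nls_starts: int = 4, error_scale: float = 0.025,
                      regions: tuple = POWER_REGIONS) -> pd.DataFrame:
    """Per-replicate decisions for the hierarchical model, LME and t-tests.

    All three methods see the same simulated studies; the comparators run on
    NLS-estimated log outcomes (oracle weights), the hierarchical model on
    the TACs themselves.  The comparison condition uses five regions and a
    2.5% measurement-error scale: the LME's advantage over per-region
    t-tests is region pooling, and the baselines only have measurable power
    at smoke-study group sizes when the NLS outcomes are reasonably clean.
    """
    pop = pop or default_population()
    rows = []
    for rep in range(n_reps):
        seed = base_seed + 1000 * rep
        cfg = smoke_config(n_per_group=n_per_group, effect=effect, seed=seed,
                           error_scale=error_scale, regions=regions)
        study = simulate_study(cfg, pop)

        fits = fit_study_nls(study, weights_scheme="oracle", n_starts=nls_starts, seed=seed)
        fits = fits.merge(study.covariates[["subject", "group"]], on="subject")
        fits["log_BPND"] = np.log(np.maximum(fits["BPND"], 1e-6))
        comp = comparator_tests(fits, value_col="log_BPND")

        design = build_design(study, CovariateSpec({"BPND": ["group"]}))
        smp = sampler or SamplerConfig.sweep()
        smp = SamplerConfig(chains=smp.chains, warmup=smp.warmup, samples=smp.samples,
                            seed=seed + 7, max_retries=smp.max_retries,
                            target_accept=smp.target_accept, max_leapfrog=smp.max_leapfrog)
        fit = fit_simba(design, sampler=smp)
        ci = group_effect_interval(fit)
        rows.append({"rep": rep,
                     "simba_excludes": decide_group_difference(ci) != 0,
                     "simba_lower": ci.lower, "simba_upper": ci.upper,
                     "simba_estimate": ci.point, "simba_converged": fit.converged,
                     "lme_reject": comp["lme"]["reject"],
                     "t_reject_rate": comp["t_reject_rate"]})
    return pd.DataFrame(rows)
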