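"""Shared fixtures.

The expensive session fixtures (replicated hierarchical-model fits) are
shared between the module tests and the acceptance suite so each sweep runs
once per session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from simbapet.blood import AIFParameters
from simbapet.harness import smoke_config
from simbapet.kinetics import FrameSchedule, RateConstants
from simbapet.simba import CovariateSpec, SamplerConfig, build_design
from simbapet.simulate import sample_truth, simulate_study, smoke_schedule


@pytest.fixture(scope="session")
def aif() -> AIFParameters:
    return AIFParameters(t0=0.5, b=160.0, tp=1.1, A1=220.0, A2=35.0, A3=8.0,
                         lambda1=3.0, lambda2=0.35, lambda3=0.02)


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return smoke_schedule()


@pytest.fixture(scope="session")
def rc() -> RateConstants:
    return RateConstants(K1=0.10, k2=0.15, k3=0.06, k4=0.028, vB=0.05)


def sweep_sampler(seed: int) -> SamplerConfig:
    """Sampler settings for single headline fits (full retry budget)."""
    return SamplerConfig(chains=2, warmup=500, samples=500, seed=seed,
                         max_leapfrog=128, max_retries=2)


def light_sampler(seed: int, max_retries: int = 1) -> SamplerConfig:
    """Lighter settings for replicated sweeps."""
    return SamplerConfig(chains=2, warmup=450, samples=400, seed=seed,
                         max_leapfrog=128, max_retries=max_retries)


@pytest.fixture(scope="session")
def smoke_study():
    """One small simulated study with a 20% BPND group effect."""
    cfg = smoke_config(n_per_group=4, effect=float(np.log(1.2)), seed=13)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def smoke_design(smoke_study):
    return build_design(smoke_study, CovariateSpec({"BPND": ["group"]}))


@pytest.fixture(scope="session")
def smoke_fit(smoke_design):
    from simbapet.simba import fit_simba

    return fit_simba(smoke_design, sampler=sweep_sampler(7))


@pytest.fixture(scope="session")
def null_simba_replicates():
    """20 hierarchical-model fits to null smoke studies (no group effect)."""
    from simbapet.harness import simba_replicates

    return simba_replicates(n_reps=20, base_seed=50_000, effect=0.0,
                            n_per_group=3, sampler=light_sampler(0))


@pytest.fixture(scope="session")
def power_comparison():
    """Method comparison at a 20% BPND effect under the power condition
    (n=4/group, 5 regions, 2.5% noise, reduced between-subject BPND spread).
    Convergence retries are disabled for this sweep; the group-effect
    marginal mixes quickly and the ordering uses only its interval."""
    from simbapet.harness import method_comparison, power_population

    return method_comparison(10, 90_000, float(np.log(1.2)),
                             pop=power_population(), n_per_group=4,
                             sampler=SamplerConfig(chains=2, warmup=500, samples=450,
                                                   seed=0, max_leapfrog=128,
                                                   max_retries=0))


@pytest.fixture(scope="session")
def values_power_comparison():
    """Multivariate vs univariate hierarchical fits to true simulated values
    (paired per replicate), n=20/group, 20% BPND effect."""
    from simbapet.simba import SamplerConfig, fit_values
    from simbapet.simulate import SimulationConfig
    from simbapet.harness import SMOKE_REGIONS
    from simbapet.evaluate import posterior_interval, decide_group_difference

    smp = SamplerConfig(chains=2, warmup=500, samples=500, seed=0,
                        max_leapfrog=64, max_retries=1)
    rows = []
    for rep in range(20):
        cfg = SimulationConfig(n_per_group=20, regions=SMOKE_REGIONS,
                               schedule=smoke_schedule(),
                               effect_log_bpnd=float(np.log(1.2)),
                               seed=31_000 + 1000 * rep)
        truth = sample_truth(cfg)
        row = {"rep": rep}
        for mv in (True, False):
            smp_r = SamplerConfig(chains=2, warmup=400, samples=400,
                                  seed=rep * 13 + (0 if mv else 7),
                                  max_leapfrog=64, max_retries=1)
            fit = fit_values(truth.params, sampler=smp_r, multivariate=mv)
            ci = posterior_interval(fit.get("beta_BPND[group]"), 0.95)
            tag = "multi" if mv else "uni"
            row[f"{tag}_excludes"] = decide_group_difference(ci) != 0
            row[f"{tag}_lower"] = ci.lower
            row[f"{tag}_upper"] = ci.upper
            row[f"{tag}_estimate"] = ci.point
        rows.append(row)
    import pandas as pd

    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def comparator_null_rates_200():
    """t-test / LME false-positive rates over 200 null outcome simulations."""
    from simbapet.harness import comparator_null_rates

    return comparator_null_rates(n_reps=200, n_per_group=20, base_seed=77)
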