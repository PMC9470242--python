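"""Hierarchical Bayesian model: design building, convergence rule, inference."""

import numpy as np
import pandas as pd
import pytest

from simbapet.evaluate import posterior_interval
from simbapet.harness import group_effect_interval, smoke_config
from simbapet.params import default_population
from simbapet.simba import (CovariateSpec, FitResult, SamplerConfig, build_design,
                            check_convergence, fit_simba, fit_values,
                            nls_parameter_count, phi_vb_parameter_count,
                            posterior_correlations)
from simbapet.simulate import SimulationConfig, sample_truth, simulate_study, smoke_schedule

from conftest import light_sampler, sweep_sampler


@pytest.fixture(scope="module")
def nine_region_design():
    cfg = SimulationConfig(n_per_group=1, schedule=smoke_schedule(),
                           error_scale=0.0, seed=40)
    study = simulate_study(cfg)
    return build_design(study, CovariateSpec({"BPND": ["group"]}))


class TestBuildDesign:
    def test_region_dummies(self, nine_region_design):
        d = nine_region_design
        assert d.n_regions == 9
        from simbapet._model import SimbaModel
        names = SimbaModel(d).names
        assert sum(n.startswith("d_K1[") for n in names) == 8
        assert sum(n.startswith("d_BPND[") for n in names) == 8

    def test_covariates_per_parameter(self, nine_region_design):
        d = nine_region_design
        assert "BPND" in d.X and d.X["BPND"].shape == (d.n_tacs, 1)
        assert "k4" not in d.X

    def test_row_counts(self, smoke_design, smoke_study):
        n_tacs = smoke_study.n_tacs
        assert smoke_design.X["BPND"].shape[0] == n_tacs
        # the error-model design has one row per observed frame
        assert smoke_design.sigma_rows == n_tacs * smoke_study.schedule.n_frames
        assert smoke_design.B.shape == (smoke_study.schedule.n_frames, 8)

    def test_missing_covariate_column(self, smoke_study):
        with pytest.raises(ValueError, match="nope"):
            build_design(smoke_study, CovariateSpec({"BPND": ["nope"]}))

    def test_missing_covariate_values(self, smoke_study):
        import copy
        study = copy.copy(smoke_study)
        cov = smoke_study.covariates.copy()
        cov.loc[cov.index[0], "age"] = np.nan
        study.covariates = cov
        with pytest.raises(ValueError, match=str(smoke_study.subjects[0])):
            build_design(study, CovariateSpec({"K1": ["age"]}))


class TestConvergenceRule:
    def _fit(self, rhat):
        k = len(rhat)
        return FitResult(draws=np.zeros((2, 4, k)), names=[f"p{i}" for i in range(k)],
                         rhat=np.asarray(rhat, float), converged=False, divergences=0,
                         attempts=1, seeds=[0], accept_rate=0.9, multivariate=True)

    def test_all_good(self):
        assert check_convergence(self._fit([1.0] * 100))

    def test_single_bad_parameter(self):
        rhat = [1.0] * 99 + [1.30]
        assert not check_convergence(self._fit(rhat))

    def test_two_percent_rule(self):
        rhat = [1.06] * 3 + [1.0] * 97  # 3% above 1.05, none above 1.25
        assert not check_convergence(self._fit(rhat))
        rhat = [1.06] * 2 + [1.0] * 98  # exactly 2% is allowed
        assert check_convergence(self._fit(rhat))

    def test_missing_rhat(self):
        with pytest.raises(ValueError):
            check_convergence(self._fit([1.0, np.nan]))


class TestSmokeFitInference:
    def test_intercepts_recovered(self, smoke_fit, smoke_study):
        """True population intercepts fall inside their 95% credible intervals
        (reference-region coding folds the first region's profile into alpha)."""
        pop = default_population()
        regions = sorted(smoke_study.regions)
        ref = regions[0]
        truths = {
            "alpha[K1]": pop.alpha["K1"] + pop.region_deviation(ref, "K1"),
            "alpha[BPND]": pop.alpha["BPND"] + pop.region_deviation(ref, "BPND"),
            "alpha[VND]": pop.alpha["VND"] + np.mean(
                [pop.region_deviation(r, "VND") for r in regions]),
            "alpha[k4]": pop.alpha["k4"] + np.mean(
                [pop.region_deviation(r, "k4") for r in regions]),
            "alpha[vB]": pop.alpha["vB"] + np.mean(
                [pop.region_deviation(r, "vB") for r in regions]),
        }
        for name, true in truths.items():
            ci = posterior_interval(smoke_fit.get(name), level=0.95)
            assert ci.lower - 0.02 <= true <= ci.upper + 0.02, (name, true, ci)

    def test_group_effect_recovered(self, smoke_fit):
        draws = smoke_fit.get("beta_BPND[group]")
        assert abs(draws.mean() - np.log(1.2)) <= 2 * draws.std(ddof=1)

    def test_posterior_correlation_matrices(self, smoke_fit):
        R = posterior_correlations(smoke_fit, "tac")
        assert R.shape[1:] == (4, 4)
        assert np.allclose(R[:50].diagonal(axis1=1, axis2=2), 1.0, atol=1e-9)
        assert np.min(np.linalg.eigvalsh(R[:50])) > -1e-9

    def test_posterior_hierarchy_deviations(self, smoke_fit, smoke_design):
        from simbapet.simba import posterior_hierarchy

        h = posterior_hierarchy(smoke_fit, smoke_design)
        assert h.tau.shape == (smoke_design.n_subjects, 4)
        assert h.upsilon.shape == (smoke_design.n_regions, 2)
        assert h.phi.shape == (smoke_design.n_tacs, 4)
        assert h.tau_vB.shape == (smoke_design.n_subjects,)
        # zero-centred pooling: deviations average out across units
        assert np.all(np.abs(h.tau.mean(axis=0)) < 0.4)


def test_prior_predictive_positivity():
    """Draws from the priors give positive rate constants and vB in (0, 1)."""
    from simbapet._model import PriorConfig

    pr = PriorConfig()
    rng = np.random.default_rng(0)
    n = 500
    log_vb = rng.normal(pr.alpha_loc["vB"], pr.alpha_scale["vB"], n) \
        + np.abs(rng.standard_t(3, n)) * pr.sd_scale_vB[0] * rng.standard_normal(n) \
        + np.abs(rng.standard_t(3, n)) * pr.sd_scale_vB[1] * rng.standard_normal(n)
    vb = np.exp(log_vb)
    assert np.all(vb > 0)
    assert np.mean(vb < 1.0) > 0.99
    for p in ("K1", "VND", "BPND", "k4"):
        logv = rng.normal(pr.alpha_loc[p], pr.alpha_scale[p], n) \
            + np.abs(rng.standard_t(3, n)) * pr.sd_scale_subject * rng.standard_normal(n)
        assert np.all(np.exp(logv) > 0)


def test_wstar_offset_supported(smoke_study):
    """The fixed weights-derived error offset enters the design and the
    likelihood remains well defined."""
    from simbapet._model import SimbaModel
    from simbapet.nls import compute_weights

    w = compute_weights(smoke_study.schedule, "duration")
    design = build_design(smoke_study, CovariateSpec({"BPND": ["group"]}),
                          wstar_weights=w)
    assert design.wstar is not None
    assert design.wstar.shape == design.y.shape
    assert np.allclose(design.wstar.mean(axis=0), 0.0, atol=1e-9)
    model = SimbaModel(design)
    lp, g = model.logp_grad(model.initial_point(np.random.default_rng(0)))
    assert np.isfinite(lp) and np.all(np.isfinite(g))


class TestStructure:
    def test_univariate_has_no_correlation_parameters(self, smoke_design):
        smp = SamplerConfig(chains=2, warmup=60, samples=60, seed=0,
                            max_leapfrog=16, max_retries=0)
        fit = fit_simba(smoke_design, sampler=smp, multivariate=False)
        assert not any(n.startswith("corr_") for n in fit.names)
        with pytest.raises(ValueError):
            posterior_correlations(fit, "tac")

    def test_retry_resets_seed_only(self, smoke_design):
        """Hopeless chains exhaust the retries and report every seed used."""
        smp = SamplerConfig(chains=2, warmup=20, samples=20, seed=3,
                            max_leapfrog=4, max_retries=2)
        fit = fit_simba(smoke_design, sampler=smp)
        if not fit.converged:
            assert fit.attempts == 3
            assert len(set(fit.seeds)) == 3

    def test_sampler_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(chains=1)
        with pytest.raises(ValueError):
            SamplerConfig(warmup=0)


class TestNullCoverage:
    def test_few_false_exclusions(self, null_simba_replicates):
        """Over 20 null smoke studies the 95% CrI excludes zero at most 3 times."""
        df = null_simba_replicates
        assert len(df) == 20
        assert int(df["excludes_zero"].sum()) <= 3


def test_subject_label_permutation_invariance():
    """Relabelling subjects must leave population-level inference unchanged."""
    cfg = smoke_config(n_per_group=3, effect=0.2, seed=60)
    study = simulate_study(cfg)
    perm = {s: p for s, p in zip(study.subjects, reversed(study.subjects))}

    import copy
    study2 = copy.copy(study)
    study2.tacs = study.tacs.assign(subject=study.tacs["subject"].map(perm))
    study2.covariates = study.covariates.assign(
        subject=study.covariates["subject"].map(perm))
    study2.aifs = {perm[s]: a for s, a in study.aifs.items()}
    study2.wb_means = {perm[s]: w for s, w in study.wb_means.items()}

    means = []
    for st in (study, study2):
        design = build_design(st, CovariateSpec({"BPND": ["group"]}))
        fit = fit_simba(design, sampler=light_sampler(11))
        means.append(group_effect_interval(fit).point)
    assert abs(means[0] - means[1]) < 0.06


def test_region_variance_shrinkage():
    """A study simulated with zero inter-regional VND variance concentrates
    the region-level SD of log VND below the prior median."""
    from scipy import stats

    pop = default_population()
    pop.sd_region = np.array([0.0, 0.05])
    for r, prof in pop.region_effects.items():
        pop.region_effects[r] = (prof[0], 0.0, prof[2], prof[3], prof[4], prof[5])
    cfg = smoke_config(n_per_group=3, effect=0.0, seed=61)
    study = simulate_study(cfg, pop)
    design = build_design(study, CovariateSpec({"BPND": ["group"]}))
    fit = fit_simba(design, sampler=light_sampler(12))
    post_median = float(np.median(np.exp(fit.get("log_sd_region[VND]"))))
    prior_median = 0.2 * float(stats.t.ppf(0.75, 3))  # half-t(3, 0.2)
    assert post_median < prior_median


def test_zero_correlation_artefact_check():
    """Studies generated without parameter correlations yield TAC-level
    posterior correlations centred near zero."""
    means = []
    for rep in range(3):
        cfg = smoke_config(n_per_group=3, effect=0.0, seed=70 + 1000 * rep,
                          correlations_on=False)
        study = simulate_study(cfg)
        design = build_design(study, CovariateSpec({"BPND": ["group"]}))
        fit = fit_simba(design, sampler=light_sampler(80 + rep))
        R = posterior_correlations(fit, "tac").mean(axis=0)
        means.append(R[np.tril_indices(4, -1)])
    avg = np.mean(means, axis=0)
    assert np.all(np.abs(avg) < 0.25)


class TestValuesModel:
    def test_univariate_structure(self):
        truth = sample_truth(smoke_config(n_per_group=3, effect=0.2, seed=62))
        smp = SamplerConfig(chains=2, warmup=150, samples=150, seed=0,
                            max_leapfrog=32, max_retries=0)
        fit = fit_values(truth.params, sampler=smp, multivariate=False)
        assert not any(n.startswith("corr_") for n in fit.names)
        fit2 = fit_values(truth.params, sampler=smp, multivariate=True)
        assert any(n.startswith("corr_tac") for n in fit2.names)

    def test_group_effect_estimable(self):
        truth = sample_truth(smoke_config(n_per_group=10, effect=0.4, seed=63))
        smp = SamplerConfig(chains=2, warmup=400, samples=400, seed=1,
                            max_leapfrog=64, max_retries=1)
        fit = fit_values(truth.params, sampler=smp)
        ci = posterior_interval(fit.get("beta_BPND[group]"), 0.95)
        assert ci.lower < 0.4 < ci.upper or abs(ci.point - 0.4) < 0.2


def test_parameter_counts():
    assert nls_parameter_count(97, 9) == 4365
    assert phi_vb_parameter_count(97, 9) == 873


def test_fit_summary_table(smoke_fit):
    s = smoke_fit.summary("alpha")
    assert set(s.columns) >= {"parameter", "mean", "sd", "lower", "upper", "rhat"}
    assert len(s) == 6
    assert (s["lower"] <= s["median"]).all() and (s["median"] <= s["upper"]).all()
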