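"""Synthetic-study generator: hierarchy, group effect, noise model, AIF draws."""

import numpy as np
import pytest

from simbapet.kinetics import predict_tac, outcomes_to_rates
from simbapet.params import PK_PARAMS, default_population, implied_cohens_d
from simbapet.simulate import (ErrorModel, SimulationConfig, generate_study, noise_sd,
                               sample_aif_parameters, sample_truth, simulate_study,
                               smoke_schedule)


def zero_variance_population():
    pop = default_population()
    pop.sd_subject = np.zeros(4)
    pop.sd_region = np.zeros(2)
    pop.sd_tac = np.zeros(4)
    pop.sd_vB = (0.0, 0.0)
    pop.sd_sigma = (0.0, 0.0)
    return pop


def cfg(n=2, effect=0.0, seed=0, regions=("DLPFC", "ACC", "Hippocampus"), err=0.1):
    return SimulationConfig(n_per_group=n, regions=regions, schedule=smoke_schedule(),
                            effect_log_bpnd=effect, error_scale=err, seed=seed)


class TestSampleTruth:
    def test_degenerate_hierarchy(self):
        pop = zero_variance_population()
        truth = sample_truth(cfg(effect=0.0), pop)
        for _, row in truth.params.iterrows():
            for p in PK_PARAMS:
                expected = pop.alpha[p] + pop.region_deviation(row["region"], p)
                assert np.isclose(row[f"log_{p}"], expected, atol=1e-12)

    def test_group_effect_location(self):
        c = cfg(n=4000, effect=0.182, regions=("DLPFC",), seed=3)
        truth = sample_truth(c)
        t = truth.params
        diff = (t.loc[t.group == 2, "log_BPND"].mean()
                - t.loc[t.group == 1, "log_BPND"].mean())
        assert abs(diff - 0.182) < 0.02

    def test_groups_identical_except_bpnd(self):
        c = cfg(n=4000, effect=0.5, regions=("DLPFC",), seed=4)
        t = sample_truth(c).params
        for p in ("K1", "VND", "k4"):
            d = (t.loc[t.group == 2, f"log_{p}"].mean()
                 - t.loc[t.group == 1, f"log_{p}"].mean())
            assert abs(d) < 0.02

    def test_seeded_determinism(self):
        a = sample_truth(cfg(seed=9)).params
        b = sample_truth(cfg(seed=9)).params
        c = sample_truth(cfg(seed=10)).params
        assert a.equals(b)
        assert not a.equals(c)

    def test_outcome_identities_hold(self):
        t = sample_truth(cfg(seed=1)).params
        assert np.allclose(t["VT"], t["VND"] * (1 + t["BPND"]), rtol=1e-10)
        assert np.allclose(t["VT"], t["VND"] + t["BPP"], rtol=1e-10)

    def test_subject_covariance_recovered(self):
        pop = default_population()
        c = cfg(n=5000, regions=("DLPFC",), seed=5)
        truth = sample_truth(c, pop)
        tau = truth.tau[list(PK_PARAMS)].to_numpy()
        target = np.outer(pop.sd_subject, pop.sd_subject) * pop.corr_subject
        emp = np.cov(tau.T)
        assert np.linalg.norm(emp - target) / np.linalg.norm(target) < 0.05

    def test_correlations_off(self):
        c = SimulationConfig(n_per_group=5000, regions=("DLPFC",),
                             schedule=smoke_schedule(), correlations_on=False, seed=6)
        truth = sample_truth(c)
        tau = truth.tau[list(PK_PARAMS)].to_numpy()
        corr = np.corrcoef(tau.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_unknown_region_error(self):
        with pytest.raises(ValueError):
            sample_truth(cfg(regions=("Nonexistent",)))


class TestNoiseModel:
    err = ErrorModel(error_scale=0.10, tau_sigma={"s1": 0.0, "s2": np.log(2)},
                     upsilon_sigma={"A": 0.0, "B": 0.3},
                     smooth_amplitude=0.0, smooth_timescale=3.0)

    def test_global_scale(self):
        sd = noise_sd(self.err, np.array([10.0]), "s1", "A", mean_tac=100.0)
        assert np.isclose(sd[0], 10.0)

    def test_subject_deviation_multiplies(self):
        a = noise_sd(self.err, np.array([10.0]), "s1", "A", 100.0)
        b = noise_sd(self.err, np.array([10.0]), "s2", "A", 100.0)
        assert np.isclose(b[0], 2 * a[0])

    def test_smooth_term_monotone(self):
        err = ErrorModel(error_scale=0.1, tau_sigma={"s": 0.0}, upsilon_sigma={"A": 0.0},
                         smooth_amplitude=0.5, smooth_timescale=3.0)
        t = np.array([0.5, 2.0, 10.0, 50.0])
        sd = noise_sd(err, t, "s", "A", 100.0)
        assert np.all(np.diff(sd) < 0)  # decaying smooth term

    def test_zero_scale(self):
        assert np.all(noise_sd(
            ErrorModel(0.0, {"s": 0.0}, {"A": 0.0}, 0.5, 3.0),
            np.array([1.0, 2.0]), "s", "A", 100.0) == 0.0)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            cfg(err=-0.1)


class TestGenerateStudy:
    def test_tac_count(self):
        c = SimulationConfig(n_per_group=10, schedule=smoke_schedule(), seed=2)
        study = simulate_study(c)
        assert study.n_tacs == 10 * 2 * 9 == 180
        assert len(study.tacs) == 180 * smoke_schedule().n_frames

    def test_noise_free_matches_forward_model(self):
        c = cfg(err=0.0, seed=7)
        study = simulate_study(c)
        t = study.truth["params"]
        g = study.tacs[(study.tacs.subject == t["subject"][0])
                       & (study.tacs.region == t["region"][0])].sort_values("frame_start")
        rc = outcomes_to_rates(K1=t["K1"][0], VND=t["VND"][0], BPND=t["BPND"][0],
                               k4=t["k4"][0], vB=t["vB"][0])
        pred = predict_tac(rc, study.aifs[t["subject"][0]],
                           study.subject_wb_means(t["subject"][0]), study.schedule)
        assert np.allclose(g["value"].to_numpy(), pred.values, rtol=1e-9)

    def test_noise_sd_calibration(self):
        """Replicate noise draws standardised by the stated SDs are unit-SD."""
        c = cfg(n=1, regions=("DLPFC",), seed=8)
        truth = sample_truth(c)
        rng = np.random.default_rng(0)
        aifs = {s: sample_aif_parameters(rng) for s in truth.subjects}
        clean_study = generate_study(truth, aifs, noise_seed=1)
        sds = truth.noise_sds
        zs = []
        import pandas as pd
        base = None
        for rep in range(300):
            st = generate_study(truth, aifs, noise_seed=1000 + rep)
            v = st.tacs.sort_values(["subject", "region", "frame_start"])["value"].to_numpy()
            if base is None:
                cfree = cfg(n=1, regions=("DLPFC",), seed=8, err=0.0)
                tr0 = sample_truth(cfg(n=1, regions=("DLPFC",), seed=8))
                tr0.error.error_scale = 0.0
                st0 = generate_study(tr0, aifs, noise_seed=0)
                base = st0.tacs.sort_values(["subject", "region", "frame_start"])["value"].to_numpy()
            zs.append((v - base) / sds.T.ravel())
        z = np.concatenate(zs)
        assert abs(np.std(z) - 1.0) < 0.05

    def test_missing_aif_error(self):
        truth = sample_truth(cfg(seed=1))
        with pytest.raises(ValueError):
            generate_study(truth, {})

    def test_full_reproducibility(self):
        a = simulate_study(cfg(seed=11)).tacs
        b = simulate_study(cfg(seed=11)).tacs
        assert a.equals(b)


class TestAIFGenerator:
    def test_invariants_and_decay(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            a = sample_aif_parameters(rng)  # constructor enforces invariants
            peak = a.b * (a.tp - a.t0)
            from simbapet.blood import aif_value
            assert peak > aif_value(a, 90.0)

    def test_seeded(self):
        assert sample_aif_parameters(seed=4) == sample_aif_parameters(seed=4)
        assert sample_aif_parameters(seed=4) != sample_aif_parameters(seed=5)


def test_implied_cohens_d():
    assert np.isclose(implied_cohens_d(default_population(), 0.182), 0.55, atol=0.005)
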