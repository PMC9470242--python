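"""Synthetic PET study generator.

Emulates the simulation design used to evaluate the hierarchical model:
log-scale pharmacokinetic parameters vary across subjects and TACs as
(multivariate) normal draws around a fixed regional profile, one group
receives a location shift on log BPND, and frame noise is Gaussian with an SD
following a log-linear model (global scale proportional to the mean TAC
value, subject and region deviations, and a smooth time component).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _forward
from .blood import AIFParameters, aif_frame_means
from .io import StudyDataset
from .kinetics import FrameSchedule, outcomes_to_rates, rates_to_outcomes
from .params import PK_PARAMS, REGION_PK, PopulationParameters, default_population

__all__ = [
    "SimulationConfig", "SimulationTruth", "ErrorModel",
    "default_schedule", "smoke_schedule",
    "sample_truth", "sample_aif_parameters", "generate_study",
    "simulate_study", "noise_sd",
]


def default_schedule() -> FrameSchedule:
    """20 frames: 3 x 20 s, 3 x 1, 3 x 2, 2 x 5, 9 x 10 min (110 min)."""
    return FrameSchedule.from_durations([1 / 3] * 3 + [1.0] * 3 + [2.0] * 3 + [5.0] * 2 + [10.0] * 9)


def smoke_schedule() -> FrameSchedule:
    """Reduced 12-frame schedule for fast simulation sweeps (57 min)."""
    return FrameSchedule.from_durations([0.5] * 2 + [1.0] * 2 + [2.0] * 2 + [5.0] * 2 + [10.0] * 4)


@dataclass
class SimulationConfig:
    n_per_group: int = 10
    regions: tuple = tuple(k for k in (
        "DLPFC", "MPFC", "ACC", "PCC", "Hippocampus", "Amygdala",
        "Parahippocampus", "Insula", "DRN"))
    schedule: FrameSchedule = field(default_factory=default_schedule)
    effect_log_bpnd: float = float(np.log(1.2))   # 20% group difference
    error_scale: float = 0.10                     # global noise SD / mean TAC value
    correlations_on: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.error_scale < 0:
            raise ValueError("error_scale must be non-negative")


@dataclass
class ErrorModel:
    """Log-linear measurement-error model for the simulator."""

    error_scale: float
    tau_sigma: dict          # subject -> log-SD deviation
    upsilon_sigma: dict      # region  -> log-SD deviation
    smooth_amplitude: float
    smooth_timescale: float

    def f(self, t):
        return self.smooth_amplitude * np.exp(-np.asarray(t, dtype=float) / self.smooth_timescale)


def noise_sd(err: ErrorModel, t_mid, subject: str, region: str, mean_tac: float):
    """Per-frame noise SD: exp(log(scale * mean_tac) + tau_s[j] + ups_s[k] + f(t))."""
    if err.error_scale < 0:
        raise ValueError("error_scale must be non-negative")
    if err.error_scale == 0:
        return np.zeros_like(np.asarray(t_mid, dtype=float))
    base = np.log(err.error_scale * mean_tac)
    return np.exp(base + err.tau_sigma[subject] + err.upsilon_sigma[region] + err.f(t_mid))


@dataclass
class SimulationTruth:
    config: SimulationConfig
    population: PopulationParameters
    subjects: list
    groups: dict                    # subject -> 1 or 2
    regions: list
    tau: pd.DataFrame               # per subject: K1, VND, BPND, k4, vB, sigma
    params: pd.DataFrame            # per TAC: log params, natural rates, outcomes
    error: ErrorModel = None
    noise_sds: np.ndarray = None    # (F, N), filled by generate_study
    mean_tac: float = None

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["schedule"] = {"start": self.config.schedule.start.tolist(),
                           "end": self.config.schedule.end.tolist()}
        d = {
            "config": cfg,
            "population": self.population.to_dict(),
            "subjects": self.subjects,
            "groups": self.groups,
            "regions": self.regions,
            "tau": self.tau.to_dict(orient="list"),
            "params": self.params.to_dict(orient="list"),
            "error": {"error_scale": self.error.error_scale,
                      "tau_sigma": self.error.tau_sigma,
                      "upsilon_sigma": self.error.upsilon_sigma,
                      "smooth_amplitude": self.error.smooth_amplitude,
                      "smooth_timescale": self.error.smooth_timescale} if self.error else None,
            "mean_tac": self.mean_tac,
        }
        if self.noise_sds is not None:
            d["noise_sds"] = self.noise_sds.tolist()
        return d


def _mvn(rng, sd, corr, n, correlated: bool) -> np.ndarray:
    sd = np.asarray(sd, dtype=float)
    z = rng.standard_normal((n, sd.size))
    if correlated:
        z = z @ np.linalg.cholesky(corr).T
    return z * sd


def sample_truth(cfg: SimulationConfig, pop: PopulationParameters | None = None) -> SimulationTruth:
    """Draw subject- and TAC-level parameter deviations and assemble true rates.

    Regional deviations are fixed at the population profile; subjects and TACs
    get fresh (multivariate) normal draws; group 2 receives the log-BPND shift.
    """
    pop = pop or default_population()
    for r in cfg.regions:
        if r not in pop.region_effects:
            raise ValueError(f"region {r!r} has no population profile")
    try:
        np.linalg.cholesky(pop.corr_subject)
        np.linalg.cholesky(pop.corr_tac)
        np.linalg.cholesky(pop.corr_region)
    except np.linalg.LinAlgError as e:
        raise ValueError("population correlation matrices must be positive definite") from e

    rng = np.random.default_rng(cfg.seed)
    J = 2 * cfg.n_per_group
    subjects = [f"s{i + 1:03d}" for i in range(J)]
    groups = {s: (1 if i < cfg.n_per_group else 2) for i, s in enumerate(subjects)}
    regions = list(cfg.regions)
    K = len(regions)

    tau_pk = _mvn(rng, pop.sd_subject, pop.corr_subject, J, cfg.correlations_on)
    tau_vb = rng.standard_normal(J) * pop.sd_vB[0]
    tau_sg = rng.standard_normal(J) * pop.sd_sigma[0]
    phi_pk = _mvn(rng, pop.sd_tac, pop.corr_tac, J * K, cfg.correlations_on)

    tau = pd.DataFrame(tau_pk, columns=list(PK_PARAMS))
    tau.insert(0, "subject", subjects)
    tau["vB"] = tau_vb
    tau["sigma"] = tau_sg

    rows = []
    n = 0
    for j, s in enumerate(subjects):
        for k, r in enumerate(regions):
            logp = {}
            for p_i, p in enumerate(PK_PARAMS):
                v = pop.alpha[p] + pop.region_deviation(r, p) + tau_pk[j, p_i] + phi_pk[n, p_i]
                if p == "BPND" and groups[s] == 2:
                    v += cfg.effect_log_bpnd
                logp[p] = v
            log_vb = pop.alpha["vB"] + pop.region_deviation(r, "vB") + tau_vb[j]
            rc = outcomes_to_rates(K1=np.exp(logp["K1"]), VND=np.exp(logp["VND"]),
                                   BPND=np.exp(logp["BPND"]), k4=np.exp(logp["k4"]),
                                   vB=float(np.exp(log_vb)))
            out = rates_to_outcomes(rc)
            rows.append({
                "subject": s, "region": r, "group": groups[s],
                **{f"log_{p}": logp[p] for p in PK_PARAMS}, "log_vB": log_vb,
                "K1": rc.K1, "k2": rc.k2, "k3": rc.k3, "k4": rc.k4, "vB": rc.vB,
                "VT": out.VT, "VND": out.VND, "BPP": out.BPP, "BPND": out.BPND,
            })
            n += 1
    parm = pd.DataFrame(rows)

    err = ErrorModel(error_scale=cfg.error_scale,
                     tau_sigma={s: float(tau_sg[j]) for j, s in enumerate(subjects)},
                     upsilon_sigma={r: pop.region_deviation(r, "sigma") for r in regions},
                     smooth_amplitude=pop.smooth_amplitude,
                     smooth_timescale=pop.smooth_timescale)
    return SimulationTruth(config=cfg, population=pop, subjects=subjects, groups=groups,
                           regions=regions, tau=tau, params=parm, error=err)


def sample_aif_parameters(rng=None, seed: int | None = None) -> AIFParameters:
    """Draw a plausible AIF from documented default ranges.

    t0 in [0.3, 1] min, rise duration in [0.3, 1.5] min, peak in [60, 120]
    kBq/mL; decay rates log-uniform over fast/medium/slow decades with the
    fast rate capped so the fast amplitude stays bounded; the tail is anchored
    to the peak value so the curve is continuous at tp by construction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t0 = rng.uniform(0.3, 1.0)
    dtp = rng.uniform(0.3, 1.5)
    peak = rng.uniform(60.0, 120.0)
    lam1 = np.exp(rng.uniform(np.log(2.0), np.log(min(6.0, 3.0 / dtp))))
    lam2 = np.exp(rng.uniform(np.log(0.2), np.log(0.6)))
    lam3 = np.exp(rng.uniform(np.log(0.01), np.log(0.04)))
    fr = np.array([0.70, 0.22, 0.08]) * rng.uniform(0.8, 1.2, size=3)
    fr = fr / fr.sum()
    amps = fr * peak * np.exp(np.array([lam1, lam2, lam3]) * dtp)
    return AIFParameters(t0=float(t0), b=float(peak / dtp), tp=float(t0 + dtp),
                         A1=float(amps[0]), A2=float(amps[1]), A3=float(amps[2]),
                         lambda1=float(lam1), lambda2=float(lam2), lambda3=float(lam3))


def generate_study(truth: SimulationTruth, aifs: dict, cfg: SimulationConfig | None = None,
                   noise_seed: int | None = None) -> StudyDataset:
    """Simulate noisy TACs from the truth and per-subject AIFs.

    The study holds n_per_group x 2 x n_regions TACs.  Whole-blood frame
    means are the AIF frame averages (constant blood:plasma ratio).  Noise is
    Gaussian, unbounded, with the per-frame SDs of the truth's error model
    anchored at ``error_scale`` times the grand mean of the noise-free TACs.
    """
    cfg = cfg or truth.config
    missing = [s for s in truth.subjects if s not in aifs]
    if missing:
        raise ValueError(f"missing AIF for subjects: {missing}")
    sched = cfg.schedule
    F = sched.n_frames
    subjects, regions = truth.subjects, truth.regions
    N = len(subjects) * len(regions)

    parm = truth.params
    aif_rows = np.stack([_forward.aif_row(aifs[s]) for s in subjects])
    aif_idx = np.repeat(np.arange(len(subjects)), len(regions))
    cb_subj = np.stack([aif_frame_means(aifs[s], sched) for s in subjects], axis=1)  # (F, J)
    cb = cb_subj[:, aif_idx]

    clean = np.empty((F, N))
    _forward.tac_batch(parm["K1"].to_numpy(), parm["VND"].to_numpy(),
                       parm["BPND"].to_numpy(), parm["k4"].to_numpy(),
                       parm["vB"].to_numpy(), sched.midpoint, aif_rows,
                       aif_idx, cb, clean)

    mean_tac = float(np.mean(clean))
    truth.mean_tac = mean_tac
    sds = np.empty((F, N))
    for n in range(N):
        s, r = parm["subject"].iloc[n], parm["region"].iloc[n]
        sds[:, n] = noise_sd(truth.error, sched.midpoint, s, r, mean_tac)
    truth.noise_sds = sds

    rng = np.random.default_rng(cfg.seed + 1 if noise_seed is None else noise_seed)
    noisy = clean + rng.standard_normal((F, N)) * sds

    rows = []
    for n in range(N):
        for i in range(F):
            rows.append({"subject": parm["subject"].iloc[n], "region": parm["region"].iloc[n],
                         "frame_start": sched.start[i], "frame_end": sched.end[i],
                         "value": noisy[i, n]})
    tacs = pd.DataFrame(rows)

    cov_rng = np.random.default_rng(cfg.seed + 2)
    covariates = pd.DataFrame({
        "subject": subjects,
        "group": [truth.groups[s] for s in subjects],
        "age": np.round(cov_rng.uniform(20, 65, size=len(subjects)), 1),
        "sex": cov_rng.choice(["F", "M"], size=len(subjects)),
    })
    wb_means = {s: cb_subj[:, j] for j, s in enumerate(subjects)}
    return StudyDataset(tacs=tacs, covariates=covariates, schedule=sched,
                        aifs={s: aifs[s] for s in subjects}, wb_means=wb_means,
                        truth=truth.to_dict())


def simulate_study(cfg: SimulationConfig, pop: PopulationParameters | None = None) -> StudyDataset:
    """Convenience wrapper: sample truth, draw per-subject AIFs, generate TACs."""
    truth = sample_truth(cfg, pop)
    rng = np.random.default_rng(cfg.seed + 3)
    aifs = {s: sample_aif_parameters(rng) for s in truth.subjects}
    return generate_study(truth, aifs, cfg)
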