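"""Population-level parameter sets for the hierarchical model and simulator.

The defaults below describe a serotonergic-tracer-like study: a moderate-flow
tracer with regionally heterogeneous specific binding (high in limbic cortex,
low in a small brainstem nucleus that is also noisier than cortical regions),
near-constant non-displaceable binding across regions, and log-scale
between-subject variation of 10-35% per parameter.  They are documented,
overridable configuration values, not estimates from any particular dataset.

Parameter order conventions used throughout the package:

* multivariate subject / TAC blocks: (log K1, log VND, log BPND, log k4)
* multivariate region block:         (log VND, log k4)
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

PK_PARAMS = ("K1", "VND", "BPND", "k4")
REGION_PK = ("VND", "k4")

__all__ = ["PK_PARAMS", "REGION_PK", "PopulationParameters", "default_population",
           "implied_cohens_d", "DEFAULT_REGIONS"]


def _corr(pairs: dict, dim: int) -> np.ndarray:
    R = np.eye(dim)
    for (i, j), r in pairs.items():
        R[i, j] = R[j, i] = r
    return R


# fixed regional deviation profile (log scale, additive to alpha)
DEFAULT_REGIONS = {
    #            K1     VND    BPND    k4     vB    sigma
    "DLPFC":   ( 0.10,  0.02,  0.10,  0.00,  0.00,  0.00),
    "MPFC":    ( 0.10,  0.00,  0.15,  0.02,  0.02,  0.00),
    "ACC":     ( 0.05,  0.03,  0.20, -0.02,  0.05,  0.05),
    "PCC":     ( 0.05, -0.02,  0.10,  0.00,  0.03,  0.00),
    "Hippocampus": (-0.10, 0.02, 0.45, 0.03, -0.02, 0.05),
    "Amygdala":    (-0.15, -0.03, 0.30, 0.02, 0.00, 0.10),
    "Parahippocampus": (-0.10, 0.00, 0.25, 0.00, 0.00, 0.05),
    "Insula":  ( 0.00,  0.02,  0.30, -0.02,  0.04,  0.00),
    "DRN":     (-0.30, -0.05, -0.40,  0.05,  0.05,  0.40),
}


@dataclass
class PopulationParameters:
    """Global intercepts, hierarchy SDs/correlations, and regional profile."""

    alpha: dict = field(default_factory=dict)        # log-scale intercepts per parameter
    sd_subject: np.ndarray = None                    # (4,) over PK_PARAMS
    corr_subject: np.ndarray = None                  # (4,4)
    sd_region: np.ndarray = None                     # (2,) over REGION_PK
    corr_region: np.ndarray = None                   # (2,2)
    sd_tac: np.ndarray = None                        # (4,)
    corr_tac: np.ndarray = None                      # (4,4)
    sd_vB: tuple = (0.20, 0.10)                      # (subject, region)
    sd_sigma: tuple = (0.20, 0.15)                   # (subject, region)
    region_effects: dict = field(default_factory=dict)  # name -> 6-tuple, columns as DEFAULT_REGIONS
    smooth_amplitude: float = 0.5                    # f(t) = amplitude * exp(-t/timescale)
    smooth_timescale: float = 3.0

    def __post_init__(self):
        for name in ("sd_subject", "sd_region", "sd_tac"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        for name in ("corr_subject", "corr_region", "corr_tac"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if not np.allclose(v, v.T) or np.any(np.diag(v) != 1.0):
                    raise ValueError(f"{name} must be symmetric with unit diagonal")
                if np.min(np.linalg.eigvalsh(v)) <= 0:
                    raise ValueError(f"{name} must be positive definite")
                setattr(self, name, v)

    def smooth_f(self, t):
        """Smooth time component of log measurement error."""
        return self.smooth_amplitude * np.exp(-np.asarray(t, dtype=float) / self.smooth_timescale)

    def region_deviation(self, region: str, param: str) -> float:
        cols = ("K1", "VND", "BPND", "k4", "vB", "sigma")
        return float(self.region_effects[region][cols.index(param)])

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def default_population() -> PopulationParameters:
    """Default ground-truth population values (see module docstring)."""
    return PopulationParameters(
        alpha={"K1": np.log(0.09), "VND": np.log(0.60), "BPND": np.log(2.5),
               "k4": np.log(0.025), "vB": np.log(0.05)},
        sd_subject=np.array([0.15, 0.20, 0.331, 0.10]),
        corr_subject=_corr({(0, 1): 0.45, (0, 2): 0.30, (0, 3): -0.10,
                            (1, 2): 0.75, (1, 3): 0.30, (2, 3): 0.10}, 4),
        sd_region=np.array([0.07, 0.05]),
        corr_region=_corr({(0, 1): 0.2}, 2),
        sd_tac=np.array([0.07, 0.10, 0.12, 0.05]),
        corr_tac=_corr({(0, 1): 0.30, (0, 2): 0.20, (0, 3): 0.00,
                        (1, 2): 0.40, (1, 3): 0.20, (2, 3): 0.10}, 4),
        region_effects=dict(DEFAULT_REGIONS),
    )


def implied_cohens_d(pop: PopulationParameters, effect_log_bpnd: float) -> float:
    """Standardised group difference implied by a log-BPND shift.

    The shift acts at the subject level, so d = effect / sd_subject(log BPND).
    """
    return float(effect_log_bpnd / pop.sd_subject[PK_PARAMS.index("BPND")])
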