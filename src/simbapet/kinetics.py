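"""Two-tissue compartment (2TC) forward model.

The measured regional PET signal is modelled as

    C_T(t) = (1 - vB) * (IRF (x) C_P)(t) + vB * C_B(t)

where C_P is the metabolite-corrected arterial plasma input (AIF), C_B the
whole-blood activity, vB the fractional blood volume, and the impulse
response function of the 2TC model is the bi-exponential

    IRF(t) = phi1 * exp(-theta1 t) + phi2 * exp(-theta2 t).

Because the AIF is parametric (zero baseline, linear rise, tri-exponential
tail; see :mod:`simbapet.blood`), the convolution has a closed form, which is
what makes whole-study likelihood evaluations cheap enough for MCMC.

All times are in minutes, concentrations in kBq/mL, rate constants in 1/min
(K1 in mL/cm^3/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateConstants",
    "BindingOutcomes",
    "ExpIRF",
    "FrameSchedule",
    "PredictedTAC",
    "rates_to_outcomes",
    "outcomes_to_rates",
    "impulse_response",
    "convolve_exponential",
    "predict_tac",
]

# Decay rates closer than this (1/min) are treated as coincident and the
# convolution switches to the t*exp(-theta t) limit form.
COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class RateConstants:
    """Micro rate constants of the 2TC model plus blood volume fraction."""

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.05

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("K1, k2, k3 must be non-negative")
        if self.k4 <= 0:
            raise ValueError("k4 must be positive")
        if not (0.0 <= self.vB < 1.0):
            raise ValueError("vB must lie in [0, 1)")


@dataclass(frozen=True)
class BindingOutcomes:
    """Derived binding outcomes: VT = VND * (1 + BPND) = VND + BPP."""

    VT: float
    VND: float
    BPP: float
    BPND: float

    def __post_init__(self):
        for name in ("VT", "VND", "BPP", "BPND"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not np.isclose(self.VT, self.VND * (1.0 + self.BPND), rtol=1e-10):
            raise ValueError("VT must equal VND*(1+BPND)")


@dataclass(frozen=True)
class ExpIRF:
    """Bi-exponential impulse response, theta1 >= theta2, phi1+phi2 = K1."""

    phi1: float
    phi2: float
    theta1: float
    theta2: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.phi1 * np.exp(-self.theta1 * t) + self.phi2 * np.exp(-self.theta2 * t)


@dataclass(frozen=True)
class FrameSchedule:
    """PET frame timings (start/end in minutes)."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.shape != end.shape or start.ndim != 1:
            raise ValueError("start and end must be 1-d arrays of equal length")
        if np.any(start < 0) or np.any(end <= start):
            raise ValueError("frames require 0 <= start < end")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ValueError("frames must not overlap and must be ordered")

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        end = np.cumsum(np.asarray(durations, dtype=float))
        return cls(start=np.concatenate([[0.0], end[:-1]]), end=end)


@dataclass(frozen=True)
class PredictedTAC:
    """Model-predicted frame activities for one TAC."""

    values: np.ndarray
    schedule: FrameSchedule = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_frames,):
            raise ValueError("values must have one entry per frame")


def rates_to_outcomes(rc: RateConstants) -> BindingOutcomes:
    """Convert micro rate constants to binding outcomes.

    VT = (K1/k2)(1 + k3/k4), VND = K1/k2, BPP = K1 k3/(k2 k4), BPND = k3/k4.
    """
    if rc.k2 <= 0:
        raise ValueError("k2 must be positive to define distribution volumes")
    vnd = rc.K1 / rc.k2
    bpnd = rc.k3 / rc.k4
    return BindingOutcomes(VT=vnd * (1.0 + bpnd), VND=vnd, BPP=vnd * bpnd, BPND=bpnd)


def outcomes_to_rates(K1: float, VND: float, BPND: float, k4: float, vB: float = 0.05) -> RateConstants:
    """Invert the outcome parameterisation: k2 = K1/VND, k3 = BPND*k4."""
    if VND <= 0:
        raise ValueError("VND must be positive")
    if BPND < 0 or K1 < 0:
        raise ValueError("K1 and BPND must be non-negative")
    return RateConstants(K1=K1, k2=K1 / VND, k3=BPND * k4, k4=k4, vB=vB)


def impulse_response(rc: RateConstants) -> ExpIRF:
    """Bi-exponential decomposition of the 2TC impulse response.

    theta1,2 are the roots of x^2 - (k2+k3+k4) x + k2 k4; the discriminant
    (k2+k3+k4)^2 - 4 k2 k4 >= (k2-k4)^2 is never negative.  A (near-)repeated
    root (k3 ~ 0 and k2 ~ k4) is split symmetrically by a tiny epsilon so the
    standard formula evaluates the analytic limit without cancellation.
    """
    s = rc.k2 + rc.k3 + rc.k4
    disc = s * s - 4.0 * rc.k2 * rc.k4
    root = np.sqrt(max(disc, 0.0))
    theta1 = 0.5 * (s + root)
    theta2 = 0.5 * (s - root)
    if theta1 - theta2 < 1e-6:
        mid = 0.5 * (theta1 + theta2)
        theta1, theta2 = mid + 5e-7, mid - 5e-7
    c = rc.k3 + rc.k4
    phi1 = rc.K1 * (theta1 - c) / (theta1 - theta2)
    phi2 = rc.K1 * (c - theta2) / (theta1 - theta2)
    return ExpIRF(phi1=phi1, phi2=phi2, theta1=theta1, theta2=theta2)


def convolve_exponential(aif, theta: float, t) -> np.ndarray:
    """Closed-form (AIF (x) exp(-theta s))(t).

    Handles the three AIF pieces exactly: zero before t0, the linear rise on
    [t0, tp], and the tri-exponential tail after tp.  A tail decay rate
    coinciding with ``theta`` uses the t*exp(-theta t) limit.

    Parameters
    ----------
    aif : AIFParameters
    theta : float, > 0 (theta == 0 integrates the AIF without decay)
    t : scalar or array of times (min); values below aif.t0 give 0
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)

    t0, b, tp = aif.t0, aif.b, aif.tp
    amps = np.asarray([aif.A1, aif.A2, aif.A3], dtype=float)
    lams = np.asarray([aif.lambda1, aif.lambda2, aif.lambda3], dtype=float)

    m = t > t0
    if np.any(m):
        tm = t[m]
        U = np.minimum(tm, tp) - t0          # extent of the linear rise covered
        D = np.maximum(tm - tp, 0.0)         # time since the peak
        if theta > 1e-12:
            eD = np.exp(-theta * D)
            eF = np.exp(-theta * (tm - t0))
            lin = b * (U * eD / theta - (eD - eF) / theta**2)
        else:
            lin = 0.5 * b * U**2
        out[m] = lin

        mt = tm > tp
        if np.any(mt):
            dd = D[mt]
            tail = np.zeros_like(dd)
            for A, lam in zip(amps, lams):
                Ap = A * np.exp(-lam * (tp - t0))
                if theta > 1e-12 and abs(theta - lam) < COINCIDENT_TOL:
                    tail += Ap * dd * np.exp(-theta * dd)
                elif theta > 1e-12:
                    tail += Ap * (np.exp(-lam * dd) - np.exp(-theta * dd)) / (theta - lam)
                else:
                    tail += Ap * (1.0 - np.exp(-lam * dd)) / lam
            out2 = out[m]
            out2[mt] += tail
            out[m] = out2
    return out[0] if scalar else out


def predict_tac(rc: RateConstants, aif, cb, sched: FrameSchedule, delay: float = 0.0) -> PredictedTAC:
    """Predict frame activities: (1-vB) * tissue(t_mid) + vB * cb.

    The tissue curve is evaluated at frame midpoints.  ``cb`` holds per-frame
    whole-blood means (already on the TAC time grid); ``delay`` shifts the
    input function relative to the tissue curve.
    """
    cb = np.asarray(cb, dtype=float)
    if cb.shape != (sched.n_frames,):
        raise ValueError("cb must provide one whole-blood mean per frame")
    irf = impulse_response(rc)
    t_eval = sched.midpoint - delay
    tissue = np.where(
        t_eval > 0,
        irf.phi1 * convolve_exponential(aif, irf.theta1, np.maximum(t_eval, 0.0))
        + irf.phi2 * convolve_exponential(aif, irf.theta2, np.maximum(t_eval, 0.0)),
        0.0,
    )
    values = (1.0 - rc.vB) * tissue + rc.vB * cb
    return PredictedTAC(values=values, schedule=sched)
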