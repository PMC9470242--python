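"""Arterial input function model and whole-blood frame averaging.

The AIF is a zero baseline up to the tracer arrival time t0, a linear rise of
gradient b up to the peak time tp, and a sum of three exponentials beyond:

    AIF(t) = 0                                 for t <  t0
           = b (t - t0)                        for t0 <= t <= tp
           = sum_i A_i exp(-lambda_i (t - t0)) for t >  tp

Note the printed formula does not force the exponential tail to meet the
linear peak; the fit is left unconstrained and :func:`continuity_gap` reports
the mismatch as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares, nnls

__all__ = [
    "AIFParameters",
    "BloodSamples",
    "aif_value",
    "aif_frame_means",
    "fit_aif",
    "whole_blood_frame_means",
    "continuity_gap",
]


@dataclass(frozen=True)
class AIFParameters:
    """Linear-rise + tri-exponential arterial input function."""

    t0: float
    b: float
    tp: float
    A1: float
    A2: float
    A3: float
    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self):
        if self.t0 > self.tp:
            raise ValueError("t0 must not exceed tp")
        if self.b <= 0:
            raise ValueError("rise gradient b must be positive")
        lams = (self.lambda1, self.lambda2, self.lambda3)
        if any(a < 0 for a in (self.A1, self.A2, self.A3)):
            raise ValueError("amplitudes must be non-negative")
        if any(l <= 0 for l in lams):
            raise ValueError("decay rates must be positive")
        s = sorted(lams)
        if s[1] - s[0] < 1e-9 or s[2] - s[1] < 1e-9:
            raise ValueError("decay rates must be distinct")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3])

    @property
    def decay_rates(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])


@dataclass(frozen=True)
class BloodSamples:
    """Discrete blood measurements (plasma or whole-blood)."""

    times: np.ndarray
    concentrations: np.ndarray
    kind: str = "plasma"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be matching 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite")
        if self.kind not in ("plasma", "whole-blood"):
            raise ValueError("kind must be 'plasma' or 'whole-blood'")


def aif_value(aif: AIFParameters, t) -> np.ndarray:
    """Evaluate the piecewise AIF at time(s) t."""
    t = np.asarray(t, dtype=float)
    rel = t - aif.t0
    tail = sum(A * np.exp(-lam * np.maximum(rel, 0.0))
               for A, lam in zip(aif.amplitudes, aif.decay_rates))
    out = np.where(t < aif.t0, 0.0, np.where(t <= aif.tp, aif.b * rel, tail))
    return out if out.ndim else float(out)


def _aif_cumint(aif: AIFParameters, t) -> np.ndarray:
    """Analytic cumulative integral of the AIF from 0 to t."""
    t = np.asarray(t, dtype=float)
    u = np.clip(np.minimum(t, aif.tp) - aif.t0, 0.0, None)
    out = 0.5 * aif.b * u * u
    rel_p = aif.tp - aif.t0
    d = np.clip(t - aif.tp, 0.0, None)
    for A, lam in zip(aif.amplitudes, aif.decay_rates):
        out = out + A * np.exp(-lam * rel_p) * (1.0 - np.exp(-lam * d)) / lam
    return out


def aif_frame_means(aif: AIFParameters, sched) -> np.ndarray:
    """Exact time-averages of the AIF over each frame."""
    return (_aif_cumint(aif, sched.end) - _aif_cumint(aif, sched.start)) / sched.duration


def continuity_gap(aif: AIFParameters) -> float:
    """|linear peak - tail value at tp|; the model does not enforce 0."""
    rel = aif.tp - aif.t0
    tail = float(np.sum(aif.amplitudes * np.exp(-aif.decay_rates * rel)))
    return abs(aif.b * rel - tail)


def _pack(aif: AIFParameters) -> np.ndarray:
    return np.array([aif.t0, aif.tp - aif.t0, aif.b, aif.A1, aif.A2, aif.A3,
                     aif.lambda1, aif.lambda2, aif.lambda3])


def _unpack(x) -> AIFParameters:
    lam = np.asarray(x[6:9])
    amp = np.asarray(x[3:6])
    order = np.argsort(-lam)  # store fastest decay first
    lam = lam[order].copy()
    # keep rates strictly distinct so the parameter object validates
    for i in (1, 2):
        if lam[i - 1] - lam[i] < 1e-8:
            lam[i] = lam[i - 1] - 1e-8
    amp = amp[order]
    return AIFParameters(t0=float(x[0]), b=float(x[2]), tp=float(x[0] + x[1]),
                         A1=float(amp[0]), A2=float(amp[1]), A3=float(amp[2]),
                         lambda1=float(lam[0]), lambda2=float(lam[1]), lambda3=float(lam[2]))


def _varpro_linear(t, yn, t0, tp, lams):
    """Best non-negative (b, A1..A3) for fixed breakpoints and decay rates."""
    rise = (t >= t0) & (t <= tp)
    tail = t > tp
    M = np.zeros((t.size, 4))
    M[rise, 0] = t[rise] - t0
    for i, lam in enumerate(lams):
        M[tail, 1 + i] = np.exp(-lam * (t[tail] - t0))
    coef, _ = nnls(M, yn)
    return coef, M @ coef - yn


def fit_aif(samples: BloodSamples, n_starts: int = 10, seed: int = 0) -> AIFParameters:
    """Multi-start least-squares fit of the parametric AIF to blood samples.

    The search is a variable-projection scheme: the nonlinear parameters
    (t0, peak time, three decay rates) are optimised with bounded least
    squares while the linear amplitudes (b, A1..A3) are profiled out by
    non-negative least squares at every evaluation -- the tri-exponential
    tail is too ill-conditioned for a joint 9-parameter search.
    Concentrations are normalised to their maximum before fitting and the
    amplitude-like parameters rescaled afterwards, making the fit exactly
    scale-equivariant.
    """
    t = samples.times
    y = samples.concentrations
    if t.size < 9:
        raise ValueError("at least 9 blood samples are required to fit the AIF")
    scale = float(np.max(y))
    if scale <= 0:
        raise ValueError("all-zero (or negative) blood samples; cannot fit an AIF")
    yn = y / scale

    ipk = int(np.argmax(yn))
    tpk = t[ipk] if ipk > 0 else t[1]
    rising = np.nonzero(yn > 0.02)[0]
    t0_guess = max(0.0, t[rising[0]] - 0.5 * (t[1] - t[0])) if rising.size else 0.0
    t0_guess = min(t0_guess, 0.9 * tpk)

    rng = np.random.default_rng(seed)
    starts = [np.array([t0_guess, max(tpk - t0_guess, 0.1),
                        np.log(3.0), np.log(0.35), np.log(0.02)])]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.array([
            rng.uniform(0.5 * t0_guess, min(tpk, 1.5 * t0_guess + 0.2)),
            rng.uniform(0.3, 1.5) * max(tpk - t0_guess, 0.1),
            rng.uniform(np.log(1.0), np.log(8.0)),
            rng.uniform(np.log(0.12), np.log(0.9)),
            rng.uniform(np.log(0.006), np.log(0.08)),
        ]))

    def resid(x):
        t0, dtp = x[0], x[1]
        lams = np.exp(x[2:5])
        _, r = _varpro_linear(t, yn, t0, t0 + dtp, lams)
        return r

    lb = np.array([0.0, 0.05, np.log(0.4), np.log(0.05), np.log(1e-4)])
    ub = np.array([tpk, max(2.0 * tpk, 3.0), np.log(60.0), np.log(2.5), np.log(0.12)])

    best, best_cost = None, np.inf
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                diff_step=1e-6, max_nfev=400)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best = sol.cost, sol.x
    if best is None:
        raise RuntimeError("AIF fitting failed for every start")

    t0, dtp = best[0], best[1]
    lams = np.exp(best[2:5])
    coef, _ = _varpro_linear(t, yn, t0, t0 + dtp, lams)
    b = max(coef[0], 1e-9)
    amps = np.clip(coef[1:], 0.0, None)
    x9 = np.concatenate([[t0, dtp, b], amps, lams])
    aif = _unpack(x9)
    return AIFParameters(t0=aif.t0, b=aif.b * scale, tp=aif.tp,
                         A1=aif.A1 * scale, A2=aif.A2 * scale, A3=aif.A3 * scale,
                         lambda1=aif.lambda1, lambda2=aif.lambda2, lambda3=aif.lambda3)


def whole_blood_frame_means(samples: BloodSamples, sched) -> np.ndarray:
    """Time-averages over each frame of a monotone-cubic interpolant.

    The interpolant passes through the samples (PCHIP); outside the sampled
    span the curve is extended flat at the first/last sample value.
    """
    t = samples.times
    y = samples.concentrations
    if t.size == 0:
        raise ValueError("empty blood samples")
    if t.size == 1:
        return np.full(sched.n_frames, y[0])
    interp = PchipInterpolator(t, y)
    anti = interp.antiderivative()

    means = np.empty(sched.n_frames)
    for i, (a, b) in enumerate(zip(sched.start, sched.end)):
        lo, hi = max(a, t[0]), min(b, t[-1])
        total = 0.0
        if hi > lo:
            total += float(anti(hi) - anti(lo))
        if a < t[0]:
            total += y[0] * (min(b, t[0]) - a)
        if b > t[-1]:
            total += y[-1] * (b - max(a, t[-1]))
        means[i] = total / (b - a)
    return means
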