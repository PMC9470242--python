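"""2TC forward model: parameter algebra, impulse response, analytic convolution."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.integrate import solve_ivp

from simbapet.blood import aif_value
from simbapet.kinetics import (FrameSchedule, RateConstants, convolve_exponential,
                               impulse_response, outcomes_to_rates, predict_tac,
                               rates_to_outcomes)
from simbapet.simulate import sample_aif_parameters


def quad_convolution(aif, theta, t):
    """Independent oracle: piecewise Gauss-Legendre quadrature of
    int_0^t AIF(s) exp(-theta (t-s)) ds, split at the AIF's kink points."""
    nodes, weights = leggauss(80)
    total = 0.0
    pieces = sorted({0.0, aif.t0, min(aif.tp, t), t})
    for a, b in zip(pieces[:-1], pieces[1:]):
        if b <= a:
            continue
        s = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        f = aif_value(aif, s) * np.exp(-theta * (t - s))
        total += 0.5 * (b - a) * np.sum(weights * f)
    return total


def random_rc(rng, vB=0.05) -> RateConstants:
    return RateConstants(
        K1=float(np.exp(rng.uniform(np.log(0.03), np.log(0.3)))),
        k2=float(np.exp(rng.uniform(np.log(0.05), np.log(0.4)))),
        k3=float(np.exp(rng.uniform(np.log(0.01), np.log(0.15)))),
        k4=float(np.exp(rng.uniform(np.log(0.01), np.log(0.1)))),
        vB=vB)


class TestOutcomeAlgebra:
    def test_direct_substitution(self):
        out = rates_to_outcomes(RateConstants(K1=0.2, k2=0.1, k3=0.05, k4=0.025))
        assert (out.VND, out.BPND, out.BPP, out.VT) == (2.0, 2.0, 4.0, 6.0)

    def test_no_specific_binding_limit(self):
        out = rates_to_outcomes(RateConstants(K1=0.2, k2=0.1, k3=0.0, k4=0.025))
        assert out.BPND == 0.0 and out.VT == out.VND == 2.0

    def test_inversion(self):
        rc = outcomes_to_rates(K1=0.2, VND=2.0, BPND=2.0, k4=0.025, vB=0.05)
        assert np.isclose(rc.k2, 0.1) and np.isclose(rc.k3, 0.05)
        rc0 = outcomes_to_rates(K1=0.1, VND=1.0, BPND=0.0, k4=0.01, vB=0.0)
        assert rc0.k2 == 0.1 and rc0.k3 == 0.0

    def test_roundtrip_machine_precision(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            rc = random_rc(rng)
            out = rates_to_outcomes(rc)
            back = outcomes_to_rates(rc.K1, out.VND, out.BPND, rc.k4, rc.vB)
            for f in ("K1", "k2", "k3", "k4", "vB"):
                assert np.isclose(getattr(back, f), getattr(rc, f), rtol=1e-12)
            fwd = rates_to_outcomes(back)
            assert np.isclose(fwd.VT, out.VT, rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rates_to_outcomes(RateConstants(K1=0.1, k2=0.0, k3=0.0, k4=0.01))
        with pytest.raises(ValueError):
            outcomes_to_rates(K1=0.1, VND=0.0, BPND=1.0, k4=0.01)


class TestImpulseResponse:
    def test_one_tissue_collapse(self):
        irf = impulse_response(RateConstants(K1=0.2, k2=0.1, k3=0.0, k4=0.025))
        assert np.isclose(irf.phi1, 0.2) and abs(irf.phi2) < 1e-12
        assert np.isclose(irf.theta1, 0.1) and np.isclose(irf.theta2, 0.025)

    def test_irf_at_zero_equals_K1(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            rc = random_rc(rng)
            irf = impulse_response(rc)
            assert np.isclose(irf.phi1 + irf.phi2, rc.K1, rtol=1e-9)
            assert irf.theta1 >= irf.theta2 > 0
            assert np.isclose(irf.theta1 * irf.theta2, rc.k2 * rc.k4, rtol=1e-6)
            assert np.isclose(irf.theta1 + irf.theta2, rc.k2 + rc.k3 + rc.k4, rtol=1e-9)

    def test_matches_ode_integration(self, aif):
        """Analytic tissue curve vs a stiff integration of the 2TC system."""
        sched = FrameSchedule.from_durations([0.5] * 2 + [2.0] * 4 + [10.0] * 5)
        rng = np.random.default_rng(2)
        for _ in range(3):
            rc = random_rc(rng)

            def ode(t, y):
                cp = aif_value(aif, t)
                return [rc.K1 * cp - (rc.k2 + rc.k3) * y[0] + rc.k4 * y[1],
                        rc.k3 * y[0] - rc.k4 * y[1]]

            sol = solve_ivp(ode, [0, sched.end[-1]], [0, 0], t_eval=sched.midpoint,
                            rtol=1e-11, atol=1e-13, max_step=0.05)
            t_ode = sol.y.sum(axis=0)
            irf = impulse_response(rc)
            t_an = (irf.phi1 * convolve_exponential(aif, irf.theta1, sched.midpoint)
                    + irf.phi2 * convolve_exponential(aif, irf.theta2, sched.midpoint))
            scale = np.max(np.abs(t_ode))
            assert np.max(np.abs(t_an - t_ode) / np.maximum(np.abs(t_ode), 1e-3 * scale)) < 1e-6

    def test_coincident_roots_limit(self, aif):
        """k3 ~ 0 with k2 ~ k4 gives a (near-)repeated root; the curve must
        match a slightly separated system continuously."""
        t = np.linspace(0.5, 50, 30)
        rc_eq = RateConstants(K1=0.1, k2=0.05, k3=1e-12, k4=0.05)
        rc_near = RateConstants(K1=0.1, k2=0.0500001, k3=1e-12, k4=0.05)
        for rc_a, rc_b in ((rc_eq, rc_near),):
            va, vb = [], []
            for r in (rc_a, rc_b):
                irf = impulse_response(r)
                va.append(irf.phi1 * convolve_exponential(aif, irf.theta1, t)
                          + irf.phi2 * convolve_exponential(aif, irf.theta2, t))
            assert np.allclose(va[0], va[1], rtol=1e-4)


class TestConvolution:
    def test_textbook_two_exponential(self):
        from simbapet.blood import AIFParameters
        a = AIFParameters(t0=0.0, b=1e9, tp=0.0, A1=1.0, A2=1e-14, A3=1e-14,
                          lambda1=2.0, lambda2=0.5, lambda3=0.01)
        v = convolve_exponential(a, 1.0, 1.0)
        assert np.isclose(v, np.exp(-1) - np.exp(-2), atol=1e-9)

    def test_coincident_rate_limit(self):
        from simbapet.blood import AIFParameters
        a = AIFParameters(t0=0.0, b=1e9, tp=0.0, A1=1.0, A2=1e-14, A3=1e-14,
                          lambda1=1.0, lambda2=0.5, lambda3=0.01)
        assert np.isclose(convolve_exponential(a, 1.0, 1.0), np.exp(-1), atol=1e-9)

    def test_matches_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            a = sample_aif_parameters(rng)
            theta = float(np.exp(rng.uniform(np.log(0.01), np.log(1.0))))
            ts = np.linspace(0.4, 115.0, 12)
            analytic = convolve_exponential(a, theta, ts)
            oracle = np.array([quad_convolution(a, theta, t) for t in ts])
            scale = np.max(np.abs(oracle))
            rel = np.abs(analytic - oracle) / np.maximum(np.abs(oracle), 1e-3 * scale)
            assert np.max(rel) < 1e-4

    def test_zero_before_onset(self, aif):
        assert convolve_exponential(aif, 0.3, aif.t0 - 0.1) == 0.0


class TestPredictTAC:
    def test_pure_blood_signal(self, aif, schedule):
        cb = np.linspace(50, 5, schedule.n_frames)
        rc = RateConstants(K1=0.1, k2=0.1, k3=0.05, k4=0.02, vB=1.0 - 1e-12)
        tac = predict_tac(rc, aif, cb, schedule)
        assert np.allclose(tac.values, cb, rtol=1e-9)

    def test_no_delivery(self, aif, schedule):
        rc = RateConstants(K1=0.0, k2=0.1, k3=0.0, k4=0.02, vB=0.0)
        tac = predict_tac(rc, aif, np.ones(schedule.n_frames), schedule)
        assert np.allclose(tac.values, 0.0)

    def test_matches_quadrature(self, aif, schedule):
        rng = np.random.default_rng(4)
        cb = np.linspace(60, 4, schedule.n_frames)
        for _ in range(5):
            rc = random_rc(rng)
            tac = predict_tac(rc, aif, cb, schedule)
            irf = impulse_response(rc)
            oracle = np.array([
                (1 - rc.vB) * (irf.phi1 * quad_convolution(aif, irf.theta1, t)
                               + irf.phi2 * quad_convolution(aif, irf.theta2, t))
                + rc.vB * c
                for t, c in zip(schedule.midpoint, cb)])
            scale = np.max(np.abs(oracle))
            rel = np.abs(tac.values - oracle) / np.maximum(np.abs(oracle), 1e-3 * scale)
            assert np.max(rel) < 1e-4

    def test_one_tissue_equivalence(self, aif, schedule):
        """k3 = 0 must reproduce the one-tissue model K1 exp(-k2 t) (x) AIF."""
        rc = RateConstants(K1=0.12, k2=0.09, k3=0.0, k4=0.03, vB=0.0)
        tac = predict_tac(rc, aif, np.zeros(schedule.n_frames), schedule)
        onetc = rc.K1 * convolve_exponential(aif, rc.k2, schedule.midpoint)
        assert np.allclose(tac.values, onetc, rtol=1e-9)

    def test_monotone_in_blood_volume(self, aif, schedule):
        cb = np.linspace(60, 4, schedule.n_frames)
        base = RateConstants(K1=0.1, k2=0.12, k3=0.05, k4=0.03, vB=0.0)
        gaps = []
        for vb in (0.0, 0.3, 0.6, 0.9):
            rc = RateConstants(K1=0.1, k2=0.12, k3=0.05, k4=0.03, vB=vb)
            tac = predict_tac(rc, aif, cb, schedule)
            gaps.append(np.sum(np.abs(tac.values - cb)))
        assert all(a > b for a, b in zip(gaps[:-1], gaps[1:]))

    def test_shape_error(self, aif, schedule):
        rc = RateConstants(K1=0.1, k2=0.1, k3=0.05, k4=0.02)
        with pytest.raises(ValueError):
            predict_tac(rc, aif, np.ones(schedule.n_frames - 1), schedule)


class TestFrameSchedule:
    def test_derived_quantities(self):
        s = FrameSchedule.from_durations([0.5, 0.5, 1.0])
        assert np.allclose(s.midpoint, [0.25, 0.75, 1.5])
        assert np.allclose(s.duration, [0.5, 0.5, 1.0])

    @pytest.mark.parametrize("start,end", [([0, 1], [2, 2]), ([0, 0.5], [1, 1.5]),
                                           ([-1, 1], [0.5, 2])])
    def test_invalid_frames(self, start, end):
        with pytest.raises(ValueError):
            FrameSchedule(start=np.array(start, float), end=np.array(end, float))
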