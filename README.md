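# simbapet

Hierarchical multifactor Bayesian analysis of PET time activity curves.

Dynamic PET quantification conventionally fits a kinetic model to each
regional time activity curve (TAC) in isolation and then compares the
resulting point estimates between groups. That two-stage pipeline discards
everything the model learns between curves, and for expensive, low-n PET
studies the lost efficiency translates directly into lost statistical
power. `simbapet` implements the alternative: one joint Bayesian model for
every TAC of every subject, with partial pooling across subjects, regions
and subject×region curves, multivariate correlation structure between the
kinetic parameters, and the group comparison estimated *inside* the model.

The package is aimed at PET kinetic modellers and biostatisticians who want
to (a) fit the joint model to tabular TAC + blood data, (b) run the
conventional multi-start nonlinear-least-squares (NLS) baseline on the same
data, and (c) quantify the power / false-positive behaviour of both
pipelines by simulation.

## The model

For the two-tissue compartment (2TC) model, the measured concentration is

    C_T(t) = (1 − vB) · (IRF ⊗ C_P)(t) + vB · C_B(t),

with a bi-exponential impulse response determined by the rate constants
(K1, k2, k3, k4) and binding outcomes VT = (K1/k2)(1 + k3/k4), VND = K1/k2,
BPP = K1k3/(k2k4), BPND = k3/k4. The arterial input C_P is a linear rise
followed by three exponentials, so the convolution is closed-form. The
model estimates log(K1, VND, BPND, k4, vB) per TAC as

    log θ[j,k] = α + X β + τ[j] + υ[k] + φ[j,k],

with multivariate-normal pooling of (K1, VND, BPND, k4) across subjects and
TACs, of (VND, k4) across regions, unpooled region dummies for K1 and BPND,
and a log-linear measurement-error model with a smooth-in-time component.
Sampling is adaptive HMC with analytic gradients (numba-compiled); a fit is
declared converged when no parameter has Rhat > 1.25 and at most 2% exceed
1.05, retrying with a fresh seed otherwise. See `docs/methods.md` for the
full specification, priors, and numerical choices.

## Worked example

```python
import numpy as np
from simbapet.harness import smoke_config, group_effect_interval
from simbapet.simulate import simulate_study
from simbapet.simba import CovariateSpec, SamplerConfig, build_design, fit_simba

# simulate a small two-group study: 4 subjects/group, 3 regions, 12 frames,
# a 20% group difference in BPND, noise SD 10% of the mean TAC value
cfg = smoke_config(n_per_group=4, effect=np.log(1.2), seed=13)
study = simulate_study(cfg)

design = build_design(study, CovariateSpec({"BPND": ["group"]}))
fit = fit_simba(design, sampler=SamplerConfig.sweep(seed=7))

print(fit.converged, round(float(fit.rhat.max()), 3))
ci = group_effect_interval(fit, level=0.95)
print(f"group effect on log BPND: {ci.point:+.3f} [{ci.lower:+.3f}, {ci.upper:+.3f}] Pd={ci.pd:.3f}")
```

Output from this exact configuration:

```
True 1.04
group effect on log BPND: +0.355 [-0.119, +0.800] Pd=0.944
```

The fit converged (max Rhat 1.04). The posterior group difference in
log BPND is +0.36 with Pd = 0.944 — a 94% posterior probability that the
effect is positive — but the 95% credible interval still includes zero:
four subjects per group simply cannot pin down a 20% difference, which is
the power problem the method exists to quantify. The point estimate tracks
the realised difference between the eight sampled subjects in this
replicate (+0.26) rather than the population value log(1.2) = 0.182;
both the estimate and the interval width honestly reflect that
small-sample variation.

The same study can be pushed through the conventional pipeline with
`simbapet.nls.fit_study_nls` and `simbapet.evaluate.comparator_tests`
(per-region Welch t-tests and a random-intercept LME), and whole sweeps are
orchestrated by `simbapet.harness`. A `simba` command-line tool wraps the
library (`simba simulate`, `fit-nls`, `fit-simba`, `evaluate`,
`power-study`).

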