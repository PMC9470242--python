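# Methods

## The model

A dynamic PET study yields, for each subject j and brain region k, a time
activity curve (TAC): radioactivity concentrations over frames i. `simbapet`
models every TAC of a study jointly with the two-tissue compartment (2TC)
model

    C_T(t) = (1 - vB) (IRF ⊗ C_P)(t) + vB C_B(t),
    IRF(t) = φ1 e^{−θ1 t} + φ2 e^{−θ2 t},

where C_P is the metabolite-corrected arterial input function (AIF), C_B the
whole-blood activity and vB the fractional blood volume. θ1,2 are the roots
of x² − (k2+k3+k4)x + k2k4 and φ1,2 follow from (K1, k2, k3, k4) by the
standard 2TC algebra. Binding outcomes are VT = (K1/k2)(1 + k3/k4),
VND = K1/k2, BPP = K1k3/(k2k4), BPND = k3/k4. The model is parameterised in
(K1, VND, BPND, k4, vB) — the biologically interpretable set — and all
parameters are log-transformed, so additive model terms act as proportional
effects and positivity is automatic.

The AIF is parametric — zero before t0, a linear rise of gradient b up to
the peak time tp, and a sum of three exponentials A_i e^{−λ_i(t−t0)}
afterwards — which gives the tissue convolution a closed form. This is what
makes joint MCMC over hundreds of TACs feasible: one likelihood evaluation
is a few thousand exponentials, not a numerical convolution.

### Hierarchical structure

Each log parameter has a global intercept α, optional covariate effects Xβ,
and partially pooled deviations per subject (τ), per region (υ) and per TAC
(φ):

| parameter | region handling | subject | TAC |
|---|---|---|---|
| log K1   | unpooled dummies | pooled (MVN) | pooled (MVN) |
| log VND  | pooled υ         | pooled (MVN) | pooled (MVN) |
| log BPND | unpooled dummies | pooled (MVN) | pooled (MVN) |
| log k4   | pooled υ         | pooled (MVN) | pooled (MVN) |
| log vB   | pooled υ (univ.) | pooled (univ.) | — |
| log σ    | pooled υ (univ.) | pooled (univ.) | — |

K1 and BPND differ across regions by orders of magnitude for many tracers,
so their regional means are unpooled fixed effects (reference coding; the
first region in sorted order is absorbed into α). VND, k4 and vB are
biologically expected to be near-constant across regions and get shrunken
regional deviations. The subject- and TAC-level 4-vectors
(log K1, log VND, log BPND, log k4) and the region-level pair
(log VND, log k4) are multivariate normal with full correlation matrices, so
well-estimated parameters stabilise poorly identified ones. vB and the
measurement error are kept out of the multivariate blocks (no biological
reason for them to inform kinetics) and get no TAC-level terms.

The frame likelihood is Gaussian, C_T(t_i) ~ N(μ_i, σ_i²), with a log-linear
error model

    log σ[i,j,k] = α_σ + X_σ β_σ + τ_σ[j] + υ_σ[k] + f(t_i),

where f is a smooth function of frame time (8 basis functions: a linear
column plus the leading eigenvectors of the double-centred |t_i − t_j|³
radial matrix, i.e. a thin-plate-style penalised basis with a shared
hierarchical scale on the coefficients). f replaces a priori frame weights;
a fixed weights-derived offset w* = −½(log w − mean log w) can be supplied
instead but is off by default. An a-priori weighting scheme is still used by
the NLS baseline.

### Priors (defaults, all overridable via `PriorConfig`)

* α: normal, centred at generic tracer-scale values
  (log 0.1, log 0.5, log 2, log 0.03, log 0.05 for K1, VND, BPND, k4, vB;
  scales 0.3–0.5). The error intercept α_σ is centred at log(0.1 × mean
  observed activity) with scale 1 — a data-scaled location, analogous to
  centring on the data scale.
* covariate effects β: normal(0, 0.3); regional dummies: normal(0, 1).
* hierarchy SDs: half-Student-t(3) with scales decreasing from subject (0.4)
  to region (0.2) to TAC (0.15) — deviations are expected to shrink down the
  hierarchy; vB (0.3, 0.15) and σ (0.3, 0.2) by level; smooth scale 0.5.
* correlation matrices: LKJ with η = 1 (subject) and η = 2 (region, TAC),
  i.e. uniform at the subject level and mild scepticism of extreme
  correlations below it.

### Sampling

No probabilistic-programming backend is part of the package's dependency
set, so sampling is a purpose-built adaptive Hamiltonian Monte Carlo:

* Non-centred parameterisation of every hierarchy level; correlation
  matrices via tanh-transformed canonical partial correlations, under which
  the LKJ density factorises into independent scaled-Beta terms (the
  per-cpc Beta shape is η + (d − 2 − j)/2 for column j — verified against
  the known LKJ marginals).
* Gradients are analytic for every linear/hierarchy/prior block; only the
  2TC forward map is differentiated by forward differences in its four
  nonlinear log parameters (step 1e−6; relative error ~1e−5, well below what
  the accept step can notice). The whole posterior gradient and the leapfrog
  trajectories are compiled (numba), ≈0.12 ms per gradient for a 24-TAC
  study.
* Warmup: dual-averaging step-size adaptation (target acceptance 0.85)
  with Stan-style expanding diagonal-mass windows; trajectory lengths are
  jittered uniformly in [L/2, L] with L = 128 for simulation sweeps (the
  variance-component funnels need long trajectories).
* Before sampling, a bounded L-BFGS ascent (hierarchy log-SDs frozen at
  their initial values so the funnels cannot collapse) moves the chains out
  of the low-density initialisation plateau; chains are then jittered.
* Convergence: a fit counts as converged iff no parameter has rank-Rhat
  above 1.25 and at most 2% exceed 1.05 (Rhat via arviz). On failure the
  model is refitted with a fresh seed only — never new data or priors — up
  to `max_retries` times.

The fit-to-values variant (`fit_values`) applies the same multifactor mean
structure directly to per-TAC log parameter values; the TAC-level
multivariate normal is then the residual distribution and carries no latent
parameters. Setting `multivariate=False` in either model replaces all
multivariate blocks by independent normals with identical priors.

## The simulator

`simbapet.simulate` generates studies from the same generative model:
subject and TAC deviations drawn from the multivariate normals, fixed
regional deviation profiles, a log-BPND location shift for group 2, and
Gaussian frame noise with SD

    exp( log(error_scale × mean TAC value) + τ_σ[j] + υ_σ[k] + f(t_i) ),

with `error_scale` = 0.10 by default (noise SD 10% of the grand-mean TAC
value — a deliberately pessimistic level) and f(t) = 0.5·exp(−t/3 min)
(higher noise in the short early frames). Ground-truth population values are
a documented configuration standing in for unavailable fitted values: a
moderate-flow serotonergic-tracer-like profile with α = log(0.09, 0.60, 2.5,
0.025, 0.05), subject-level SDs (0.15, 0.20, 0.331, 0.10) — the BPND value
chosen so a 20% group difference (Δlog = 0.182) is a d = 0.55 effect —
region-level SDs (0.07, 0.05), TAC-level SDs (0.07, 0.10, 0.12, 0.05), and a
strong subject-level VND–BPND correlation (0.75) with moderate positive
correlations elsewhere. Nine named regions span low (brainstem nucleus) to
high (limbic cortex) binding, with the brainstem region noisier.

Blood data: real studies would resample measured arterial curves; here AIFs
come from a parametric generator (t0 ∈ [0.3, 1] min, rise 0.3–1.5 min, peak
60–120 kBq/mL, fast/medium/slow decay rates log-uniform over
[2, 6]/[0.2, 0.6]/[0.01, 0.04] min⁻¹ with the fast rate capped so amplitudes
stay bounded; the tail is anchored to the peak, making the curve continuous
at tp). The whole-blood curve is taken equal to the plasma curve (constant
blood-to-plasma ratio), and whole-blood frame means are exact analytic frame
averages of the AIF. Parent-fraction modelling, TAC–AIF delay fitting and
dispersion are not simulated; delays are zero.

The default frame schedule is 3×20 s, 3×1, 3×2, 2×5, 9×10 min (20 frames,
110 min); sweeps use a reduced 12-frame, 57-min schedule.

What the simulator does **not** emulate: image reconstruction and
resolution effects, partial-volume mixing between regions, correlated
inter-regional noise, metabolite-model error, delay/dispersion
misspecification, or AIF measurement error (fits receive the true AIF
parameters). Passing tests therefore show that the estimation machinery is
correct and well calibrated under the model's own assumptions, not that the
model is robust to the ways real data violate them.

## Scaled-down evaluation conditions

The reference simulation study (50–1000 replicates at group sizes 10–100)
needs cluster time; the test-suite replications run on one CPU in minutes
and are scaled down accordingly. Sizes were fixed once, from runtime
budgets, before the statistical checks were evaluated:

* **Null coverage**: 20 replicate null studies, n = 3/group, 3 regions
  (one low-, one mid-, one high-binding), 12 frames, 10% noise; the 95% CrI
  for the group effect may exclude zero at most 3 times. Comparator
  false-positive rates use 200 null outcome simulations at n = 20/group.
* **Power ordering** (hierarchical model ≥ LME ≥ per-region t-test at a 20%
  BPND effect): 10 replicates, n = 4/group, five regions, noise scale 2.5%
  and between-subject BPND SD reduced to 0.12. Each piece of this condition
  is load-bearing: with the default SD (0.331) a 20% effect gives every
  method near-floor power at these group sizes; the LME's advantage over
  per-region t-tests is region pooling, so it needs several regions; and
  the NLS-based comparators only clear the floor when the outcome estimates
  are reasonably clean (2.5% is the lowest noise level in the error
  sensitivity sweep of the reference design). The t-test summary is the
  mean per-region rejection rate (no multiplicity correction, matching
  per-region reporting conventions). Convergence retries are disabled for
  this sweep: the ordering uses only the group-effect marginal, which mixes
  far faster than the variance components that dominate the strict Rhat
  gate.
* **Multivariate advantage**: 20 paired replicates of the fit-to-values
  model at n = 20/group; multivariate pooling must beat the univariate
  variant. The mechanism is that the strong VND–BPND correlation lets
  subject VND values absorb part of the BPND noise, shrinking the group
  effect's posterior.

Sweep fits use 2 chains × (500 warmup + 500 draws). Group-effect marginals
mix fast; the long trajectories are needed for the variance components.

## Numerical choices

* Predicted activity is evaluated at frame midpoints (frame averaging over
  the analytic curve is a possible extension; at these frame durations the
  difference is far below the noise).
* Near-coincident exponential rates: when θ1 − θ2 < 1e−6 min⁻¹ the roots are
  split symmetrically by 1e−6 and the standard formula evaluates the
  t·e^{−θt} limit by a centred difference, accurate to ~1e−9 with no
  catastrophic cancellation; a tail rate coinciding with θ (|θ − λ| < 1e−9)
  uses the explicit limit term.
* AIF fitting is variable projection: bounded least squares over
  (t0, rise duration, log decay rates) with the linear amplitudes profiled
  out by non-negative least squares at every evaluation; concentrations are
  max-normalised first, making the fit exactly scale-equivariant. The peak
  time is only identified up to the sample spacing around it (both branches
  interpolate the same points), so it may float within one gap.
* Continuity of the AIF at tp is not enforced (the parametric form does not
  imply it); `continuity_gap` reports the mismatch as a diagnostic.
* Whole-blood frame means for measured samples use a monotone piecewise
  cubic (PCHIP) interpolant integrated exactly over each frame, extended
  flat beyond the sampled span. This replaces the two-spline rise/descent
  fit used by external blood-processing tools.
* NLS: log-scale bounds (K1 1e−3–1, VND 0.01–20, BPND 0.01–50, k4
  1e−3–0.5, vB 1e−3–0.2), log-uniform random starts, 10 starts by default,
  trust-region least squares; simulated fits default to oracle
  inverse-variance weights (isolating model comparison from
  weighting-scheme effects), measured data to duration weights. BPND is
  always the direct ratio k3/k4.
* LME group p-values use a t reference with n_subjects − 2 degrees of
  freedom — the closed-form Satterthwaite df for the balanced two-group
  random-intercept design used throughout; if the REML optimiser fails, the
  balanced-design equivalent (pooled comparison of subject means) is used.
* Logspline power estimation fits a maximum-likelihood log-density B-spline
  (basis size chosen by AIC among {4, 5, 6, 8}, small ridge for stability)
  to the CrI bounds across simulations and reads the exceedance off its CDF;
  degenerate samples fall back to the empirical proportion with a warning.

## Known limitations

* Fixed-length jittered HMC is less adaptive than NUTS; heavy funnels in
  weakly identified variance components (TAC-level SDs at smoke-study sizes)
  mix slowest and dominate the convergence budget.
* The smooth error basis is a thin-plate-style eigenbasis, not an exact
  reproduction of any specific regression-spline implementation; with ≤20
  frames the spanned function space is comparable.
* Model comparison via PSIS-LOO/LOOIC and the effective-parameter count are
  out of scope, as are reference-tissue models, delay/dispersion estimation
  and occupancy or free-fraction extensions.
* Very high binding (BPND ≫ 10) at short schedules leaves the VND/BPND split
  weakly identified; NLS then shows the classic low-k4/high-VT degeneracy.
  This is a property of the data, not the optimiser, and is precisely the
  regime where hierarchical pooling helps.
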