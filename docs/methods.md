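# Methods

`pulmo_uq` calibrates a one-dimensional pulse-wave model of the mouse
pulmonary arterial tree to pressure data by Bayesian inference, with
explicit treatment of *model mismatch*: the combined effect of model
discrepancy (the mathematical model is not the real system) and a wrong
noise model (assuming independent errors when they are correlated).  This
note records the model, the numerical choices, the synthetic-data
generator, and the design decisions taken where more than one reasonable
option existed.

## Haemodynamic model

Each vessel is a straight elastic tube carrying the cross-sectionally
averaged mass and momentum balance

    dA/dt + dq/dx = 0
    dq/dt + d(q²/A)/dx + (A/ρ) dp̃/dx = −2πμ r q / (ρ δ A)

with area A (cm²), flow q (ml/s), density ρ = 1.055 g/ml, viscosity
μ = 0.049 g/(cm·s), and the Stokes boundary-layer thickness
δ = √(μT/2πρ) entering the friction term (T = 0.11 s is the mouse cardiac
period).  Pressures are mmHg at every interface; internally everything is
cgs with the exact conversion 1333.22 applied once.

Two wall laws close the system:

* linear elastic: p = (4/3) χ (√(A/A₀) − 1),
* empirical nonlinear: p = χ tan[(π/γ)(A/A₀ − 1)], which bounds the lumen
  area by A∞ = A₀(1 + γ/2).  The argument of the tangent is read as π/γ
  (not π·γ): only this reading makes γ the parameter "setting the maximal
  lumen area", and it keeps A∞ > A₀ over the whole prior range
  γ ∈ (1, 2π).

The stiffness χ = Eh/r₀ is either constant, exponential in the unstressed
radius (χ = f₁ e^{f₂ r₀} + f₃), or vessel-specific (hierarchical model
below).  Terminal vessels carry three-element Windkessel (RCR) outlets

    dp/dt − R₁ dq/dt = q (R₁+R₂)/(R₂C) − p/(R₂C).

The capacitance is stored in the dimensionally consistent unit
ml·cm·s²/g; the reciprocal form that sometimes appears in print is not an
admissible capacitor unit.

### Nominal Windkessel parameters

Only scaling factors (ψ₁, ψ₂, c) of nominal RCR values are inferred.  The
nominal values are computed from the mean state: the total resistance
R_tot = conv·p̄/q̄ is distributed over root-to-leaf branches in proportion
to the terminal r₀⁴ (Poiseuille weighting), each branch subtracts its
root-to-leaf Poiseuille path resistance 8μL/(πr₀⁴), and the remainder is
split R₁ : R₂ = 0.2 : 0.8 with C = τ/R₂, τ = 0.025 s.  By construction
the parallel combination of (path + R₁ + R₂) reproduces p̄/q̄ exactly.
Defaults: p̄ = 17 mmHg with the default inflow's mean flow.

## Numerics

Interior: Richtmyer two-step Lax–Wendroff on (A, q), second order in space
and time, with the pressure term in conservation form through the flux
potential B(A) (closed form for both wall laws since vessels are
straight).  Friction enters the half step as (Δt/4)(S_j + S_{j+1}) and the
full step as (Δt/2)(S_{j−1/2} + S_{j+1/2}).

Boundaries are closed by the outgoing Riemann invariants W± = u ± φ(A),
φ(A) = ∫ c/A' dA' (closed form for the linear wall; 8-point Gauss–Legendre
quadrature for the nonlinear wall), integrated along the characteristic
with a predictor–corrector pass: the characteristic foot and the friction
source are re-centred on the provisional t+Δt boundary solution, keeping
the closure second order in time.  The resulting nonlinear systems are
solved by damped Newton iteration (tolerance 1e-10 on nondimensional
residuals, at most 30 iterations):

* inlet: prescribed q plus the outgoing W⁻ (1 unknown);
* junctions: three outgoing characteristics, two pressure continuities,
  one flow conservation (6 unknowns; residuals scaled by reference wave
  speeds, stiffness, and A₀c₀);
* outlets: outgoing W⁺ plus the trapezoidal discretization of the
  Windkessel ODE (2 unknowns).

Each simulation runs whole cardiac cycles until the maximum relative
cycle-to-cycle pressure change falls below 1e-3 (at most 10 cycles by
default) and reports the last cycle.  A smooth half-sine ramp multiplies
the inflow during the first cycle only, suppressing the impulsive start-up
transient; warm starts from a neighbouring parameter point's final state
(used heavily inside MCMC) skip the ramp and typically converge in 2–3
cycles.  The CFL number is monitored every step and the solver aborts
beyond 1.  `stable_dt` chooses Δt from the stiffest vessel's rest wave
speed with a safety factor 0.35, per proposal, so one chain can cross the
whole stiffness prior box.

Observed convergence order on a smooth (C∞) inflow is ≈ 2.2 in the L2
norm and ≈ 1.8 in the max norm; the default squared-sine inflow is only
C¹ at the systole boundaries, which caps the observed max-norm order near
1.3 along the characteristics emanating from those kinks (an expected
property of Lax–Wendroff on data with jumps in curvature, not a solver
defect).

Reference discretization: Δx = 0.025 mm, Δt = 1.34e-5 s (CFL ≈ 0.97 at
χ ≈ 5e4).  Desk-scale analyses use Δx = 0.05 cm with `stable_dt`; at this
resolution a 3-vessel forward solve costs milliseconds, which is what
makes joint PDE–MCMC tractable on one CPU.

## Error models

With model output m(θ, t) and data y(t):

* iid: y ~ N(m, σ²I); σ² carries the conjugate IG(0.001, 0.001) prior and
  is updated by Gibbs steps.
* GP mismatch: y = m + Γ, Γ(t) = f(t) + u(t), f ~ GP(0, K(w, b)),
  u ~ N(0, σ_n²I), so C = K + σ_n²I.  K is the non-stationary
  neural-network (arcsine) covariance
  k(t,t') = (2/π)·asin(2(b + w t t') / √((1+2(b+w t²))(1+2(b+w t'²)))),
  with exactly two hyperparameters (bias variance b, weight variance w),
  log-uniform priors on the printed ranges w ∈ (1, 9)·10⁴, b ∈ (1, 500),
  kernel inputs in unscaled seconds.  σ_n² gets the same IG prior as σ²
  (its prior is not printed anywhere; the conjugate weakly informative
  choice mirrors the iid case).  Model discrepancy and noise-model error
  are not separately identifiable and are represented by the single GP.

Multi-vessel data form independent blocks sharing one set of error
parameters (the pressure transducer does not depend on the measurement
site); no cross-vessel covariance is modelled.

For WAIC under the correlated likelihood, per-observation terms are the
univariate conditionals obtained from the Cholesky factor of C
(log p(y_i | y_1..y_{i−1})); they sum to the joint log-likelihood exactly,
preserving the additive structure WAIC needs.  Whether to use conditional
or joint per-point terms is a genuine convention choice; the conditional
decomposition is the package default because it keeps n points per vessel.

## Priors and samplers

Biophysical parameters carry rescaled beta(1,1) (uniform) priors on the
printed physiological boxes.  Sampling is adaptive random-walk Metropolis
on transformed coordinates (logit for box-bounded parameters, logit in
log-space for log-uniform ones, log for variances) with the exact Jacobian
correction.  The proposal covariance is re-estimated every 100 iterations
from the most recent half of the history (scaled 2.38²/d), the global
scale is tuned toward acceptance 0.25, and adaptation freezes at burn-in
(first half of the chain).  Restricting the covariance estimate to the
recent history matters: it raises the effective sample size of the
strongly correlated biophysical block by an order of magnitude on the desk
problems.  σ² (iid case) is updated by its conjugate Gibbs step each
iteration.  Chains are bit-reproducible given the seed.

### Hierarchical vessel-specific stiffness

Population law χ_j ~ N(m_χ, σ_χ²) truncated to χ_j > 0, with hyperpriors
m_χ ~ N(6·10⁴, (2.15·10⁴)²) and σ_χ² ~ IG(2, 1.75·10⁸).  These constants
were calibrated once by Monte Carlo so the prior predictive places 90.0%
of its mass on the printed range (2, 10)·10⁴ g cm⁻¹ s⁻²; that printed 90%
constraint is the only published anchor for the hyperpriors.  Sampling is
Gibbs-within-Metropolis: conjugate normal/inverse-gamma updates of
(m_χ, σ_χ²) — ignoring the truncation correction, which is negligible for
the calibrated hyperpriors — log-scale Metropolis updates of each χ_j
(one forward solve per proposal, per-coordinate scale adaptation to
acceptance 0.44), and a joint Metropolis block for (ψ₁, ψ₂, c) and the
error parameters.  The model collapses to shared stiffness as σ_χ² → 0
and decouples the χ_j as σ_χ² → ∞; both limits are exercised in the test
suite, and the Gibbs conditionals are validated against closed-form and
grid-integration oracles on frozen (analytic) forward models.

## Posterior emulation

Two surrogates are provided.

1. A GP emulator of the log-posterior surface (anisotropic squared
   exponential + nugget on unit-box-scaled, log-transformed coordinates;
   seeded Latin-hypercube design, marginal-likelihood fit, and a
   refinement stage).  Refinement uses an upper-confidence acquisition
   (predicted mean + 2 predictive standard deviations over candidates
   drawn half uniformly and half around the best design points): pure
   maximum-variance refinement spreads points over the prior box, whose
   volume is astronomically larger than the posterior's support, and was
   measured to leave the surface useless exactly where the posterior mass
   sits.  Log-posterior values more than 50 nats below the running maximum
   are clipped before fitting (relative density < e⁻⁵⁰ is irrelevant to
   the chain and the huge dynamic range otherwise dominates the fit).

2. An emulator of the forward map θ → m(θ, t) (multi-output GP with a
   shared kernel over the biophysical box), with the error-model
   likelihood then evaluated *analytically* in (σ²) or (w, b, σ_n²).
   Only the PDE solve is expensive, so emulating the output and keeping
   the error parameters exact is both cheaper and far more accurate than
   emulating the full joint surface; it is the configuration used by the
   pipeline's emulated runs and validated in the fidelity tests
   (emulated-vs-direct Kolmogorov–Smirnov distance below 0.1 on every
   marginal of the 7-parameter mismatch model).

MCMC against either surrogate needs no PDE solves and runs two orders of
magnitude faster than direct sampling.  The emulated posterior also makes
an excellent preconditioner: passing its unconstrained-space covariance to
the direct sampler (`MCMCSettings.init_cov`) removes the isotropic
start-up transient, which the fidelity tests rely on to obtain a direct
reference chain with enough effective samples for a Kolmogorov–Smirnov
comparison at desk scale.

## Synthetic-data generator

The generator emulates the study conditions end to end:

* a parametric inflow (squared-sine ejection, t_sys = 0.04 s of T = 0.11 s,
  peak 1.3 ml/s, 7% reverse lobe, near-zero diastole) calibrated once so
  that the forward model at plausible posterior-median parameters yields a
  systolic MPA pressure inside the physiological 12–35 mmHg window;
* a synthetic binary tree stand-in for the unpublished micro-CT geometry
  (root radius 0.047 cm, per-generation radius ratio 0.79 with a seeded
  left/right asymmetry so the two lungs receive unequal flow, lengths
  L = 10 r₀); 11 terminals give the 21-vessel reference network;
* error-free pressures from the forward model at the reference truth
  (linear wall, radius-dependent stiffness, f₁ = 5.11e6, f₂ = −171,
  f₃ = 4.32e4, ψ = (0.29, 0.87, 1.34) — plausible posterior-median
  values; the study's exact generating values are not published, so
  Table-level error statistics are reproducible only approximately);
* correlated noise drawn from MVN(0, a²(K(w,b) + σ_n²I)) with
  w = 5.39e4, b = 138, σ_n² = 0.05 shared by all observed vessels.  The
  amplitude a² is calibrated *per instantiation* so the realized variance
  ratio var(signal)/var(noise), averaged over observed vessels, equals
  the target (100) exactly; a² is recorded with the dataset so the
  generating covariance of every instantiation is fully specified (the
  whitening test uses it);
* rejection of any instantiation whose cycle-averaged noisy pressures
  violate proximal-to-distal monotonicity along observed parent→child
  edges (cycle averages are used because pointwise noise crossings are
  physiologically meaningless; the functional is not specified by the
  study).  At most 1000 redraws per instantiation, with the rejection
  count reported.

What the generator does *not* emulate: the measurement chain (catheter
dynamics, 5 kHz sampling, ECG-gated cycle averaging), vessel taper,
network-geometry uncertainty, or viscoelastic wall behaviour.  Passing the
synthetic-recovery tests therefore demonstrates correctness of the
inference machinery under the assumed data-generating process, not
robustness to every real-data artifact.

## Desk-scale study conditions

The replicated experiments in the test suite run on a 3-vessel tree
(MPA + daughters) at Δx = 0.05 cm with 64 observation points per cycle,
10 noise instantiations, chains of 1200 iterations (2500 for the
three-vessel-data arm, which carries three likelihood blocks), initialized
at the data-generating parameters to shorten burn-in in the recovery
studies.  These sizes are the package's desk defaults; the full-scale
analysis (21 vessels, printed-resolution grid, 150 000–300 000 iterations)
uses the same code paths with larger settings.

Two desk-scale observations worth recording:

* The f₂ marginal under multi-vessel data is *not* perfectly uniform: the
  corner of the (f₁, f₂) box where f₁e^{f₂r₀} drives χ far above the
  pressure-sensitive regime is excluded by the likelihood, which
  suppresses roughly the f₂ > −130 cm⁻¹ range when f₁ is large.  This is
  a structural property of the printed prior box (the published median
  marginal density of f₂ at the truth, 0.004, equals the uniform density
  1/250 — consistent with near-uniformity *at the truth*, which our
  posteriors reproduce — but a Kolmogorov–Smirnov distance from the exact
  uniform law remains ≈ 0.2 at any chain length).
* Interval bands: the prediction band is clipped to contain the credible
  band pointwise (the predictive law includes the explanatory
  uncertainty; finite-sample quantile noise could otherwise violate the
  nesting by epsilon).

## Known limitations

* Vessel taper, junction minor losses, viscoelastic walls, 3D/FSI
  effects, and structured-tree outflow models are out of scope.
* The conjugate hyperparameter updates of the hierarchical model ignore
  the positivity truncation of the population law (error is ~10⁻³ of the
  population mass for the calibrated hyperpriors).
* The log-posterior surface emulator degrades in more than ~5 effective
  dimensions; the forward-map emulator is the recommended surrogate.
* Exact reproduction of the published WAIC values and posterior medians
  would require the measured pressure/flow data and the unpublished
  micro-CT geometry; all quantitative checks here run on the synthetic
  stand-ins.
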