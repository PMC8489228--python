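# Methods

This note documents the models implemented in `thermoquant`, the numerical
choices behind the fits, what the synthetic-data generators do and do not
emulate, and the design decisions taken where several defensible options
existed.

## Melting-curve models

All melting models describe the measured signal as a linear-baseline mixture
of conformational states. For two-state models,

S(T) = (bN + kN·(T − Tref))·(1 − fu) + (bU + kU·(T − Tref))·fu,

with Tref fixed to the first temperature of the fitted range so that the
intercepts and slopes are decorrelated. The three-state variants add a
population-weighted intermediate term with an offset-only baseline bI: a
short-lived intermediate rarely supports an identifiable slope, and dropping
it removes one poorly determined parameter.

**Two-state equilibrium.** ΔG(T) = ΔHu·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm)),
Ku = exp(−ΔG/RT), fu = Ku/(1+Ku), with R = 8.314 J mol⁻¹ K⁻¹. ΔCp defaults
to 0 and is user-settable; with ΔCp = 0, fu(Tm) = 1/2 exactly and
Tonset (fu = 1%) has the closed form ΔHu·Tm/(ΔHu + R·Tm·ln 99). The
implementation finds Tonset by Brent root-finding on fu(T) − 0.01
(tolerance 1e-9 K) so that the same path works for ΔCp ≠ 0; the closed form
serves as a cross-check in the tests. The unfolded fraction is evaluated
through the logistic function of −ΔG/RT, which is overflow-safe for extreme
enthalpies.

**Two-state irreversible.** First-order kinetics N → U with Arrhenius rate
k(T) = exp[(Ea/R)(1/Tf − 1/T)] min⁻¹, where Tf is the temperature at which
k = 1 min⁻¹; during a ramp at scan rate v (K/min),
fu(T) = 1 − exp[−(1/v)∫k dT′]. The integral is evaluated by the trapezoid
rule on a 30× refined grid and interpolated back; at this refinement the
discretization error is below 1e-5 in fu (checked against a 10× finer grid).
The apparent midpoint of this model shifts up with scan rate, which is the
experimental signature distinguishing kinetic from equilibrium unfolding.

**Three-state equilibrium.** N ⇌ I ⇌ U with two Gibbs–Helmholtz constants
(ΔH1, Tm1) and (ΔH2, Tm2); fN = 1/(1 + K1 + K1K2), fI = K1·fN,
fU = K1K2·fN, summing to one by construction.

**Empirical models.** Logistic fu = 1/(1 + exp((Tm − T)/s)) with steepness
s > 0 (one transition), or two logistics combined as fN = 1 − f1,
fI = f1(1 − f2), fU = f1f2 (two transitions). Near Tm the logistic with
s = R·Tm²/ΔHu is the first-order expansion of the thermodynamic model, which
is why empirical Tm estimates agree closely with thermodynamic ones; the
empirical models carry no ΔG and are excluded from ΔG(25 °C) ranking.

**Derived stability quantities.** Tonset (1% unfolded), ΔG at 25 °C
(298.15 K), and ranking of conditions by Tm, Tonset or ΔG25 in descending
order with ties broken by well id; flagged fits are listed separately rather
than silently dropped.

## Fitting machinery

All fits run through bounded trust-region least squares
(`scipy.optimize.least_squares`). Standard errors are asymptotic: the
Jacobian-based covariance (JᵀJ)⁻¹ scaled by the residual variance
SSR/(n − p); 95% intervals are estimate ± 1.96·SE. Profile-likelihood or
bootstrap intervals would be less model-dependent but are slower and
stochastic; the asymptotic choice keeps every fit deterministic —
identical inputs give bit-identical results. Non-convergence triggers one
deterministic restart from a start nudged 25% toward the bound-box midpoint;
if that also fails the fit is returned with the NOT_CONVERGED flag rather
than raising. A constant input trace short-circuits to CONSTANT_SIGNAL
without fitting.

Initial guesses for melt fits: Tm from the maximum of |dS/dT| after a
3-point median smooth (grid midpoint fallback when the derivative carries no
transition signature, in which case the fit is usually flagged); baselines
from least-squares lines over the first and last 10% of points; ΔHu seeded
at 300 kJ/mol, a typical protein value. Default bounds: Tm within the fitted
range ± 5 K, ΔHu ∈ [10, 2000] kJ/mol; steepness s ∈ [0.05, 50] K. Bounds
exist partly so that "estimate too close to a bound" is a meaningful quality
signal.

Quality filters: REL_ERR_GT_50 when any thermodynamic parameter (baselines
exempt — near-zero slopes legitimately have huge relative errors) has a
relative standard error above 50% (configurable); NEAR_BOUNDARY when any
estimate lies within 1% of the bound span of either bound (the proximity
fraction is configurable; 1% is a pragmatic reading of "too close").
Binding-level warnings LOW_AMPLITUDE (response range too small to constrain
Kd) and NO_SHIFT (all Tm shifts < 0.2 K) extend the same flag vocabulary.
Flags annotate rather than auto-exclude: the user decides.

## Isothermal and Tm-shift binding analysis

The isothermal route assumes the ligand binds only the native state, so a
stabilizing ligand raises the apparent Tm and lowers fu at fixed T. Step 1
fits every curve of the titration with the apparent two-state model
(ΔCp = 0), locally per curve or globally with shared baseline slopes
(kN, kU); sharing only the slopes is the minimal global constraint and is
configurable. Step 2 evaluates fu at one temperature Ti from each curve's
(ΔH_obs, Tm_obs) and fits

fu = Ku/(Ku + 1 + Lfree/Kd),

with Lfree from the exact mass-balance quadratic
x² + x(Kd(Ku+1) + Ptot − Ltot) − Ltot·Kd(Ku+1) = 0, evaluated in a
cancellation-safe form. The 1:2 variant uses the independent-two-site
binding polynomial with Lfree from bisection on [0, Ltot] (the residual is
monotone, so the bracket is guaranteed). Ti defaults to the Tm observed at
the lowest concentration and should sit near the free-protein Tm: the
validity of using (ΔH_obs, Tm_obs) away from the transition degrades, and
the fu dynamic range collapses — the LOW_AMPLITUDE warning encodes this.

Ku and Kd are fitted in log10 space (bounds 10⁻¹²–10⁻¹ M, spanning
picomolar to the high-millimolar regime), which enforces positivity and
makes the error model multiplicative. Consequence: the stored fitted
parameter is log10(Kd/M), for which the ±1.96·SE interval is exact; the
linear-scale Kd is reported as a derived quantity with the asymmetric
interval 10^(x ± 1.96·SE). The delta-method SE on linear Kd is deliberately
not reported, as it is misleading when the log-scale SE is large.

The Tm-shift route assumes Lfree = Ltot and a temperature-independent Kd,
solving −ΔHu(1 − T/Tm0)/(RT) = ln(1 + Ltot/Kd) for the predicted Tm at each
concentration (Brent, 1e-9 K) and least-squares fitting the observed Tm
values, with (ΔHu, Tm0) fixed from the zero/lowest-ligand curve or co-fitted.
Because the two routes make different approximations they agree only within
a factor of ~2 on the same data (verified on synthetic series); the
isothermal estimate is the more principled one when ligand depletion
matters (Ptot comparable to Kd).

## MST analysis

Fnorm is the mean fluorescence over a hot window divided by the mean over a
cold window; t = 0 (IR switch-on) is assigned to the hot side, so the
defaults cold [−1, 0] s / hot [0, 2] s partition the trace cleanly. Fnorm is
reported as a raw ratio (multiply by 1000 for the per-mille convention); any
uniform gain cancels. The initial-fluorescence QC fails a capillary whose
cold mean deviates more than 20% from the across-capillary average —
beyond that, the ligand itself perturbs the fluorophore and the binding
signal is suspect; QC failures warn and annotate rather than auto-exclude
(exclusion is an explicit option).

The response model is RF1·(1 − fb) + RF2·fb, the linear combination of the
unbound and complexed signals. For 1:1 binding, fb comes from the exact
mass-balance quadratic (no free-ligand approximation), evaluated in the
cancellation-safe form 2·Ltot/(S + √(S² − 4·Ptot·Ltot)). Two-site models
use independent sites with identical or distinct constants; the response
weight is the average site occupancy. Kd is fitted in log10 space as above.
The LOW_AMPLITUDE warning compares the fitted response range *over the
measured concentrations* to 3× the residual noise — using |RF2 − RF1|
directly would be wrong, since RF1 is unconstrained when the curve
saturates below the lowest measured point.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (scenario, seed) and carry their ground
truth, so recovery tests are exact by construction.

* **DSF plates** — model signal plus i.i.d. Gaussian noise scaled to a
  fraction of the unfolding amplitude (default 0.5%, typical of nanoDSF).
  Presets: a 96-well two-state screening plate (Tm spread 318–338 K,
  ΔHu 400 kJ/mol), a pH-screen-like plate with monotone Tm across ten
  conditions, and a two-transition curve (dominant low-T step plus a minor
  high-T step).
* **Ligand series** — melting curves generated from the *coupled*
  equilibrium: Ku(T) from Gibbs–Helmholtz, Lfree solved at every
  temperature, fu = Ku/(Ku + 1 + Lfree/Kd). Defaults: 16 concentrations,
  1.5-fold dilution from 150 µM, Ptot = 15 µM, free Tm = 315.15 K (42 °C),
  ΔHu = 400 kJ/mol, Kd = 2 µM. Note the generated curves are *not* exactly
  two-state at any single concentration — which is precisely what makes
  recovery through the apparent-two-state step a meaningful test. (The
  quoted experimental design's bottom concentration of 0.068 µM is
  inconsistent with 16 points at 1.5-fold from 150 µM, which ends at
  0.34 µM; the generator follows the top/factor/count.)
* **MST traces** — cold plateau F0, then F0·[1 − A(fb)·(1 − e^(−t/τ))]
  with the T-jump amplitude A interpolating linearly between unbound (0.10)
  and bound (0.22) levels and τ = 1.2 s; 16 capillaries, 2-fold dilution
  from 150 µM, Ptot = 25 nM, 0.5% trace noise. An optional multiplicative
  gain jitter exercises the ±20% QC. This is a single-exponential caricature
  sufficient to exercise window logic and Fnorm arithmetic; it contains no
  thermophoresis physics (no Soret depletion, no back-diffusion, no
  bleaching), so passing tests validate the *analysis chain*, not any claim
  about real TRIC kinetics.

Real instrument data additionally contain correlated baseline drift,
capillary artefacts, aggregation spikes and scan-to-scan gain variation that
the generators do not model; the spike-smoothing and QC steps exist for
those, and are exercised with synthetic spikes/outliers instead.

## Problem sizes in the test suite

The suite runs the full designs where the guarantee is quantitative: the
96-well recovery plate, 50-seed isothermal and MST recovery (16 curves or
capillaries each), 10⁴ random draws for solver-versus-oracle equivalence,
and 200 repeated fits for the CI-coverage check ([0.90, 0.99] for Tm).
Unit tests use smaller instances of the same generators (12-well plates,
10²–10³ draws) since they check structure rather than rates. Round-trip
I/O properties run on 20 seeded random fixtures per dialect.

## Known limitations

* Binding to the unfolded state is not modelled; a destabilizing
  (unfolded-state-binding) ligand violates the isothermal model's
  assumptions.
* The Tm-shift model uses a temperature-independent Kd (no van 't Hoff
  correction) and the Lfree = Ltot approximation.
* Asymptotic CIs undercover when parameters are near bounds or the noise is
  far from Gaussian; the CI-coverage test bounds this only for the
  well-behaved two-state case.
* The two-site MST model shares one response pair (RF1, RF2) across sites;
  per-site responses are not identifiable from a single titration.
* The empirical three-state model assumes sequential logistics (the second
  transition acts on the unfolded share of the first).
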