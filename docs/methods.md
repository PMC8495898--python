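# Methods

## The measurement model

The extended kinetic (Cooks) method determines the gas-phase acidity of an
analyte acid AH — the Gibbs free-energy change GA = Δ_acid G° of
AH → A⁻ + H⁺ at 298.15 K — from the competitive collision-induced
dissociation (CID) of mass-selected proton-bound heterodimer anions
[A·H·A_ref(i)]⁻ formed with a *ladder* of reference acids of known
deprotonation enthalpy Δ_acid H°_ref(i) and entropy Δ_acid S°_ref(i).
Each heterodimer dissociates into either the analyte anion A⁻ or the
reference anion A_ref(i)⁻, with rate constants k and k_i.  Neglecting
secondary fragmentation and reverse activation barriers, the abundance
ratio of the two fragment channels equals k/k_i, and its logarithm is
linear in the thermochemical difference between the two acids:

```
ln([A⁻]/[A_ref(i)⁻]) = (ΔH_ref(i) − ΔH)/(R·T_eff) + (ΔS − ΔS_ref(i))/R
```

where T_eff is the *effective temperature*, a phenomenological parameter
characterizing the internal excitation of the dissociating population.
T_eff is treated purely as a regression parameter (no RRKM or
density-of-states modelling) and, empirically, rises roughly linearly with
the center-of-mass collision energy E_CM = E_lab·m/(M + m) (collision-gas
mass m, heterodimer mass M).

The simple kinetic method drops the entropic term; the *extended* method
keeps it, at the price of fitting two strongly correlated parameters.  The
decorrelated formulation centers the reference enthalpies on their ladder
mean ΔH_ref^avg and proceeds in two regression stages:

1. **First thermokinetic plots** — at each collision energy, regress
   y = ln([A⁻]/[A_ref(i)⁻]) on x = ΔH_ref(i) − ΔH_ref^avg.  The slope is
   1/(R·T_eff); the intercept is −[(ΔH − ΔH_ref^avg)/(R·T_eff) − Δ(ΔS°)/R],
   with Δ(ΔS°) = ΔS − ΔS_ref^avg.
2. **Second thermokinetic plot** — across collision energies, regress the
   negated first-plot intercepts on the first-plot slopes.  The line's
   slope is ΔH − ΔH_ref^avg and its intercept is −Δ(ΔS°)/R, so the two
   parameters are read off from orthogonal features of one line.

Back-substitution of the ladder averages gives ΔH and ΔS = Δ(ΔS°) +
ΔS_ref^avg, and GA = ΔH − T·ΔS at T = 298.15 K.  The validity of replacing
the per-reference entropy by the ladder average rests on the references
having similar deprotonation entropies; see *Limitations*.

## Estimators and uncertainty propagation

**Stage 1.** Replicate acquisitions are averaged on the ln-ratio scale
(the scale on which the model is linear), with the standard error over
replicates as the point uncertainty.  The line is fitted by weighted least
squares with weights 1/σ_y² when every point has a positive uncertainty,
and by ordinary least squares otherwise (e.g. single replicates).  The
(slope, intercept) covariance is (XᵀWX)⁻¹ for the weighted fit and the
residual-based s²(XᵀX)⁻¹ for OLS.  A fit with a non-positive slope would
imply a negative T_eff; it is flagged and excluded from stage 2 with a
warning rather than aborting the run.

**Stage 2.** Both coordinates of a second-plot point inherit uncertainty
from the same stage-1 covariance matrix, including their mutual
covariance (the sign flip of the intercept negates the off-diagonal
term).  The line is therefore fitted by an effective-variance
(York-type) errors-in-both-variables estimator, minimizing

```
χ²(a, b) = Σ_i [y_i − a − b·x_i]² / (σ_y,i² + b²σ_x,i² − 2b·σ_xy,i)
```

via York's fixed-point iteration on the slope, initialized at the OLS
solution.  The iteration is run to the floating-point fixed point (well
inside the nominal 1e−12 relative criterion, capped at 100 iterations).
When per-point correlations are strong the raw fixed-point map can fall
into a period-2 cycle around the minimum; in that case the stationarity
residual g(b) = york_step(b) − b changes sign between the two cycle
iterates and is solved by bracketed root-finding (Brent) instead.  With
all uncertainties zero the estimator reduces exactly to the OLS closed
form.  Parameter variances come from York's adjusted-abscissa
expressions, which supply the full (slope, intercept) covariance.

**Back-substitution.** ΔH = slope₂ + ΔH_ref^avg and Δ(ΔS°) = −R·intercept₂
with R = 8.3145 J/(mol·K) exactly.  Uncertainties are propagated to first
order from the stage-2 covariance; the uncertainties of the ladder
averages (quadrature mean of the rung uncertainties) are added in
quadrature.  The GA variance retains the stage-2 slope–intercept
covariance term: the fitted enthalpy and entropy are strongly
anti-correlated, and dropping the term would overstate the GA
uncertainty — handling exactly this correlation is the purpose of the
decorrelated formulation.  All ± values are carried as 1σ standard
uncertainties, ingested as-is.

**Numerical conventions.** Enthalpies and free energies are in kJ/mol,
entropies in J/(mol·K); the single J→kJ conversion lives in
`ga_from_enthalpy_entropy`.  Collision energies within 1e−6 eV are one
energy group (set values, not measured ones).  Centering on the ladder
mean is also a conditioning choice: the analysis is invariant under any
centering constant of the ladder's own scale (verified to 1e−9), while an
off-scale center (say, 0 kJ/mol) amplifies stage-1 intercept rounding by
the ~1400 kJ/mol shift and costs about two digits.  Degenerate designs
fail loudly: a constant-T_eff experiment has no abscissa spread in the
second plot and raises an identifiability error rather than returning an
unidentifiable ΔS.

## The synthetic-data generator

No public raw branching-ratio data accompany the published barbituric-acid
measurements, so the package ships a generator that emulates an
instrument run under the analysis' own statistical assumptions:

* Forward model: the ideal ln-ratio above, with a per-reference entropy
  term, evaluated at T_eff(E_CM) = t0 + t1·E_CM.
* Defaults: truth (ΔH, ΔS) = (1389.1 kJ/mol, 93.7 J/(mol·K)) — the
  weak-site (N–H) values of barbituric acid — measured against a
  representative high-GA ladder of four benzoic-acid references with
  evenly spaced acidities spanning GA 1360.6–1390.8 kJ/mol; seven
  collision energies from 0.75 to 4.0 eV; t0 = 500 K, t1 = 150 K/eV
  (T_eff ≈ 610–1100 K over the grid); two replicates per point;
  base intensity 1e5 counts.  A low-GA ladder (1328.0–1343.5 kJ/mol)
  is provided for strong-site (C–H) style designs.  Both ladders are
  *synthetic stand-ins* with representative values, not evaluated
  literature data, and all rungs share one deprotonation entropy
  (95 J/(mol·K), ±8.4 on both coordinates).
* Noise: independent multiplicative log-normal noise on each fragment
  channel, `i = base·exp(ε)` with ε ~ N(0, σ²) and σ = 0.05 by default,
  giving additive Gaussian ln-ratio noise of variance 2σ² — consistent
  with the regression's error model while remaining a plausible
  ion-counting approximation.  Real intensity fluctuations (counting
  statistics, source drift, m/z-dependent transmission) are not modelled.
* Determinism: one integer seed drives the whole draw; the Monte-Carlo
  recovery harness gives run *i* the independent child stream
  `(seed, i)`.

The common rung entropy is not incidental: entropy heterogeneity that is
*correlated* with the enthalpy ladder leaks into the first-plot slopes and
biases the recovered ΔS even at zero noise.  This is a property of the
method, not of the implementation, and is the quantitative face of the
"references with similar deprotonation entropies" requirement.  Custom
ladders with heterogeneous entropies can be simulated to study that bias.

Because the generator realizes exactly the assumptions the estimator
makes, passing recovery tests demonstrates the correctness and
calibration of the statistical machinery — not robustness to the
systematic effects real spectra contain (secondary fragmentation,
isobaric interference, detector saturation).

## Validation performed by the test-suite and acceptance script

* Zero-noise datasets are fixed points of the full pipeline (ΔH, ΔS
  recovered to < 1e−6 across randomized admissible designs).
* Stage-1 fits agree with closed-form normal equations to 1e−10; the
  stage-2 estimator agrees with an independent brute-force minimization
  of the same χ² profile to 1e−6 relative.
* At the default design with 5% intensity noise, 200-run Monte-Carlo
  recovery yields a median |ΔH error| well under 3 kJ/mol, and the
  recovered GA falls within the published 1361.5 ± 10.5 kJ/mol band in
  ≥ 80% of runs; the 1σ reported intervals cover the truth in ≥ 55% of
  runs (the ladder-average uncertainty dominates the reported error
  budget, so coverage is conservative).
* The ΔG = ΔH − TΔS identity applied to the published barbituric-acid
  rows reproduces the printed GA values within the table's 0.5 kJ/mol
  rounding.  The published row for the 5,5-dimethyl compound is
  internally inconsistent (1404.2 − 298.15·0.1067 ≈ 1372.4 kJ/mol,
  not the printed 1369.4; consistency would need ΔS ≈ 116.7 J/(mol·K));
  it is therefore not used as a numeric fixture anywhere.

Problem sizes in the shipped tests (50 random zero-noise designs, 200
oracle instances, 200-run Monte-Carlo batches) were chosen as the package's
own validation budget; all complete in seconds.

## Limitations

* T_eff is purely phenomenological; nothing constrains its linearity in
  E_CM beyond the empirical trend, and the pipeline does not require it
  (the T_eff–E_CM correlation is reported as a diagnostic only).
* The entropy back-substitution assumes similar reference entropies (see
  above); the reported ΔS inherits any violation as bias, not as inflated
  uncertainty.
* Whether published ± values are 1σ or 95% intervals is often unstated in
  the literature; this package ingests them as 1σ without rescaling and
  records that convention in its output.
* The CLI and readers handle delimited-text branching tables only;
  extracting fragment intensities from raw or mzML spectra is upstream of
  this package.
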