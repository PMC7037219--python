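# Methods

## Model structure and assumptions

The minimal PBPK model lumps the whole body into five well-stirred
compartments: plasma, the interstitial fluid (ISF) of a tight-junction
tissue group (muscle, skin, CNS — low vascular permeability), the ISF of a
leaky tissue group (liver, spleen, gut), lymph, and a tumor. It encodes the
accepted picture of antibody disposition: convective transcapillary
transport with lymph flow (diffusion negligible for a >150 kDa protein),
the ISF as the extravascular distribution space, return to blood via lymph,
and slow linear catabolic clearance from plasma. The tumor is attached to
plasma by first-order exchange rates `kpt` (in) and `ktp` (out); recycling
of tumor drug into the lymph node compartment is neglected. No elimination
occurs in the tight, leaky or tumor compartments, and there is no
target-mediated (saturable) disposition term: the observed plasma and tumor
profiles are dose-proportional between 1 and 10 mg/kg, which a TMDD model
is neither needed for nor identifiable from (the binding/turnover
microconstants are unknown). Consequently the model is linear
time-invariant, exposures scale exactly with dose, and plasma
AUC(0–∞) = dose/CLp holds in closed form — both facts are exploited as
oracles in the test suite (a matrix-exponential solution cross-checks the
ODE integrator; the analytic AUC cross-checks the NCA layer).

The accessible ISF volume is partitioned as `Vtight = 0.65·ISF·Kp`,
`Vleaky = 0.35·ISF·Kp` and lymph flow as `L1 = 0.33·L`, `L2 = 0.67·L`. The
partition formulas use the experimentally determined tumor-to-plasma ratio
`Kp = 0.156` as the ISF-accessibility scaling, as printed in the source
parameterization; whether that symbol should instead be an independent
accessibility fraction is left as the parameterization's own convention
and implemented as printed.

## Parameters

| symbol | default | unit | role |
|--------|---------|------|------|
| L | 0.12 | mL/h | total lymph flow (fixed, literature) |
| ISF | 4.35 | mL | total interstitial fluid volume (fixed, literature) |
| Kp | 0.156 | – | tissue-to-plasma ratio (fixed, experimental) |
| Vp | 1.74 | mL | plasma volume (**fitted**) |
| Vlymph | 1.7 | mL | lymph volume (fixed, literature, as printed) |
| Vt | 0.5 | mL | tumor volume (fixed, experimental; no growth dynamics) |
| CLp | 0.0181 | mL/h | plasma clearance (**fitted**) |
| kpt | 0.00269 | 1/h | plasma→tumor rate (**fitted**) |
| ktp | 0.0602 | 1/h | tumor→plasma rate (**fitted**) |
| S1 | 0.95 | – | tight-tissue vascular reflection coefficient (fixed) |
| S2 | 0.475 | – | leaky-tissue vascular reflection coefficient (**fitted**) |
| SL | 0.2 | – | lymphatic capillary reflection coefficient (fixed) |

Reflection coefficients are constrained to [0, 1]; `S2 > S1` is *not*
enforced (the reference fit has S2 < S1). Body weight is not part of the
model; it enters only to convert mg/kg doses to amounts. The default of
0.0266 kg is a reconstruction chosen so that dose/CLp lands on the
published plasma AUC scale (1 mg/kg → 26.6 μg → 1470 h·μg/mL); it is a
configuration value, not a measured one. Tumor μg/g is treated as μg/mL
under unit tissue density, which is what makes `Ct = Xt/Vt` comparable to
gravimetric tumor data.

## Numerics

The ODE system is integrated with adaptive stiff-capable stepping (LSODA)
at rtol 1e-8; the absolute tolerance is dose-proportional (1e-10 μg per μg
of dose), so every dose level presents the solver with an identically
scaled problem and the model's exact dose linearity survives numerically
(doubling the dose doubles the stored trajectories bitwise). The state is
augmented with the cumulative centrally-cleared amount so mass balance —
remaining + eliminated = dose — can be asserted along every trajectory
(observed error ~1e-13 relative). The flux structure guarantees
nonnegative states; tolerance-level negative round-off appearing once a
trajectory decays below the absolute tolerance is clamped to zero.
Halving the tolerances moves stored concentrations by far less than 0.01%.

## Estimation

Fitting is bound-constrained least squares (trust-region reflective) on
per-timepoint *mean* concentrations, pooled across plasma and tumor and
across both dose groups with shared parameters. Destructive sampling makes
per-animal longitudinal fitting meaningless — each mouse contributes one
timepoint — so mean profiles are the natural unit. Default residual
weighting is 1/prediction² (proportional error), appropriate for
concentrations spanning ~3 orders of magnitude over 336 h; uniform and
1/prediction weightings are selectable. Standard errors come from the
asymptotic covariance s²·(JᵀJ)⁻¹ at the solution, reported as %CV
(100·SE/estimate). The optimizer start is deterministic (the fixed
parameter set, or user-supplied values); an optional seeded multi-start
adds lognormal jitter to guard against local minima, which the clean-data
fixed-point test shows is not needed in the reference geometry. Failed
simulations inside the objective return a large finite penalty with a
warning so the optimizer can retreat. When only one assay should define
the fitted data, the dataset is filtered to that assay (the reference
pipeline fits the LBA view, the platform that reads the intact molecule).

## Non-compartmental analysis

AUC uses the linear trapezoidal rule; AUC(0–∞) adds C_last/λz with λz from
an unweighted least-squares line through ln(C) of the last three
quantifiable points (user-overridable). Clearance is dose/AUC, reported
for both AUC variants with the extrapolated one primary — on the reference
profiles dose/AUC_last and dose/AUC_inf differ by ~8%, which is exactly
the discrepancy visible between a trapezoidal AUC and the published CL
values, so both are exposed rather than hidden. A terminal slope that is
nonnegative (or zero at round-off scale) yields a flagged undefined
half-life rather than a number.

Cross-assay comparison runs one-way ANOVA plus Dunnett's many-to-one test
against a reference assay. Dunnett critical values and adjusted p-values
are obtained by seeded Monte-Carlo of the null max-|t| distribution
(default 100,000 draws) — group means as independent normals scaled by
1/√n over a shared pooled-variance draw — which reproduces the two-sided t
critical value in the single-comparison limit to <1% and matches an
independent implementation's p-values to ~0.01. With destructive sampling
there is only one mean-profile AUC per assay, so the real-study comparison
reduces to percent differences with the test branch flagged as skipped;
the test branch exists for replicate-level exposures.

## Calibration and QC

The 4PL curve is parameterized
`y = bottom + (top − bottom)/(1 + (x/ec50)^(−hill))` and fitted by 1/y
weighted least squares; the LC/MS line by closed-form 1/x² weighted least
squares on area ratios. Back-calculation uses the exact analytic inverse
of each curve — responses at or beyond a 4PL asymptote are refused, not
extrapolated — with 3-significant-figure rounding available as a reporting
option rather than baked into the inverse (the inverse must round-trip
`curve(c)` to machine precision to be testable against a bisection
oracle). QC metrics follow the fit-for-purpose convention: %CV = 100·sd/mean,
%RE = 100·(mean − nominal)/nominal, pass iff |%RE| ≤ 20 (25 at LLOQ) and
%CV ≤ 20; fewer than three replicates computes but flags non-qualifying.

## Virtual studies

The generator reproduces the study conditions: single i.v. bolus at 1 and
10 mg/kg, sampling at 5 min (stored as 5/60 h) and 1, 6, 24, 72, 168, 240,
336 h, three mice per timepoint, each mouse yielding one plasma and one
tumor sample measured by all three assay platforms. Measurement scatter is
multiplicative lognormal with proportional CV 20% by default — chosen as a
realistic magnitude for combined biological-plus-assay scatter in a mouse
PK study of this kind, with the published error bars giving only a loose
visual anchor — drawn once per animal-and-matrix and shared across the
platforms measuring that same physical sample. Assay bias is a constant
multiplicative factor per (assay, matrix), defaulting to 0.67 for the
generic IgG4 peptide in tumor (the ~33% under-read, reconstructed as a
constant rather than modeled mechanistically through trypsinization or
C-terminal-lysine effects). Values below an assay's LLOQ (its bottom
calibration standard: LBA 0.586 μg/mL plasma / 0.039 μg/g tumor; LC/MS
0.10 μg/mL / 0.25 μg/g) are censored as BLQ. A dataset is fully
reproducible from (design, parameters, seed).

What the generator does *not* emulate: tumor growth over the 336 h study
(volume fixed at 0.5 mL), anti-drug-antibody formation or any time-varying
clearance, target expression heterogeneity, and any distinction between
biological and analytical variance components. Passing loop-closure tests
therefore demonstrate that the estimation machinery is correct and
well-calibrated *under the model's own assumptions*, not that the model is
the true data-generating process for a real xenograft study.

## BLQ policy

The study's source analysis never states how below-quantification values
were handled, so two explicit policies are provided and recorded in
dataset provenance: `drop` (remove BLQ records) and `zero_before_cmax`
(BLQ before the profile peak set to zero — absorption-phase convention —
and dropped after it). Neither is asserted as the original analysis's
choice; summaries always report all-BLQ cells as flagged rather than
silently absent.

## Problem sizes in the shipped checks

The reproducibility script and test suite size their simulations for a
single CPU: 100 replicate noisy studies for the ±3·SE coverage check, 1000
null trials (with a 100,000-draw critical value) for the Dunnett type-I
error, 500 replicate studies for the error-model CV calibration, and
1500–3000-point geometric time grids for the numeric-vs-analytic AUC
agreement. These sizes give Monte-Carlo standard errors comfortably inside
the asserted bands (e.g. ±0.007 on a 0.05 rejection rate at 1000 trials).

## Known limitations

- The %CV values of the published parameter fit are not exactly
  reproducible: the original objective function, weighting and covariance
  convention are unstated. The package documents its own (1/pred² WLS,
  asymptotic covariance) and claims calibration only for them.
- Mean-profile fitting understates between-animal information; a
  Bailer-type variance treatment for destructive-sampling AUC is a
  possible extension, not implemented.
- The published exposure table prints one T1/2 per dose without assay
  attribution; reports here leave that attribution open.
- No population (mixed-effects) or Bayesian estimation; no FcRn or TMDD
  submodels; no species scaling.
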