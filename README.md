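# fusionpk

Minimal physiologically based pharmacokinetic (PBPK) modeling and
bioanalytical QC for antibody-based therapeutic fusion proteins in mouse
xenograft studies.

## The problem

Therapeutic fusion proteins (an IgG backbone fused to an active protein —
here an anti-CD38 IgG4 fused to a modified interferon alpha) are dosed
systemically but act in tissue, so their evaluation hinges on two linked
questions: *how much drug reaches the tumor relative to plasma*, and
*whether the assays used to measure it agree*. Tumor exposure is measured
by orthogonal platforms — an electrochemiluminescence ligand binding assay
(LBA) and immunocapture-LC/MS (IC-LC/MS) reading either an
interferon-alpha-specific signature peptide or a generic IgG4 peptide —
which can disagree systematically (the generic IgG4 peptide under-reads
tumor by roughly a third). `fusionpk` provides, for PK scientists running
such studies:

- a **minimal PBPK model** with a tumor compartment, simulated and fitted
  simultaneously to plasma and tumor concentration–time data;
- **non-compartmental analysis** (AUC, CL, Cmax, terminal half-life) and
  cross-assay exposure comparison (one-way ANOVA + Dunnett many-to-one
  test with seeded Monte-Carlo critical values);
- **calibration-curve machinery** (4PL with 1/y weighting for LBA;
  1/x² weighted linear for LC/MS) with exact back-calculation and the
  standard %CV / %RE acceptance rules;
- a **virtual-study generator** reproducing the terminal-sampling design
  (single i.v. bolus at 1 and 10 mg/kg; sampling at 5 min, 1, 6, 24, 72,
  168, 240, 336 h; n = 3 mice per timepoint), with proportional lognormal
  error, per-assay bias, and LLOQ censoring.

## The model

Five compartments exchange drug amounts X (μg): plasma (p), interstitial
fluid of tight and leaky tissue groups, lymph, and tumor (t). Antibody
leaves plasma by convection with lymph flow L across vascular walls whose
reflection coefficients σ₁, σ₂ reject a fraction of the macromolecule,
drains to lymph past the lymphatic wall (σ_L), and returns to plasma;
tumor exchanges with plasma by first-order rates k_pt, k_tp. The only
elimination is linear plasma clearance CL_p:

```
dXp/dt     = −CLp·Cp − L1(1−σ1)·Cp − L2(1−σ2)·Cp + Clymph·L − kpt·Xp + ktp·Xt
dXtight/dt = L1(1−σ1)·Cp − Ctight·L1(1−σL)
dXleaky/dt = L2(1−σ2)·Cp − Cleaky·L2(1−σL)
dXlymph/dt = Ctight·L1(1−σL) + Cleaky·L2(1−σL) − Clymph·L
dXt/dt     = kpt·Xp − ktp·Xt
```

with C = X/V per compartment, `Vtight = 0.65·ISF·Kp`,
`Vleaky = 0.35·ISF·Kp`, `L1 = 0.33·L`, `L2 = 0.67·L`, and an i.v. bolus as
the only nonzero initial condition (all drug in plasma). The model is
linear in dose, so exposures scale exactly with dose and plasma
AUC(0–∞) = dose/CL_p in closed form. Five parameters are estimated from
data (V_p, CL_p, k_pt, k_tp, σ₂); the rest are fixed at literature or
experimental values.

## Worked example

```python
import numpy as np
from fusionpk import (simulate, mouse_reference_parameters, nca_profile,
                      analytic_plasma_auc_inf, tumor_plasma_ratio)

params = mouse_reference_parameters()
times = np.concatenate([[0.0], np.geomspace(5/60, 2000.0, 1500)])
dose_ug = 1.0 * 0.0266 * 1000          # 1 mg/kg x 26.6 g mouse
sim = simulate(params, dose_ug, times)

plasma = nca_profile(sim.times, sim.Cp, dose_ug_per_kg=1000.0)
tumor = nca_profile(sim.times, sim.Ct)
print(f"plasma AUC(0-inf) = {plasma.auc_inf:8.1f} h*ug/mL "
      f"(closed form dose/CLp = {analytic_plasma_auc_inf(params, dose_ug):.1f})")
print(f"plasma CL         = {plasma.cl_per_kg:8.3f} mL/h/kg")
print(f"terminal t1/2     = {plasma.t_half:8.1f} h")
print(f"tumor/plasma AUC  = {tumor_plasma_ratio(tumor.auc_inf, plasma.auc_inf):8.3f}")
```

prints

```
plasma AUC(0-inf) =   1469.6 h*ug/mL (closed form dose/CLp = 1469.6)
plasma CL         =    0.680 mL/h/kg
terminal t1/2     =    104.5 h
tumor/plasma AUC  =    0.156
```

— at 1 mg/kg the numeric AUC matches dose/CL_p, clearance is in the
0.5–0.7 mL/h/kg range characteristic of a stable IgG-based molecule in
mouse, the terminal half-life is on the ~100 h scale, and the
tumor-to-plasma exposure ratio equals the tissue partition coefficient
K_p = 0.156 (exact at steady state for this linear model).

Fitting a noisy virtual study closes the loop back to the generating
parameters:

```python
from fusionpk import (default_study, generate_study, ErrorModel,
                      AssayBiasModel, FitSpec, fit, fit_report)

design, params = default_study()
study = generate_study(design, params,
                       ErrorModel(proportional_cv=0.2, seed=7),
                       AssayBiasModel())
result = fit(study, FitSpec(assay="LBA"))
print(fit_report(result))
```

which recovers e.g. `Vp 1.723 mL (CV 4.3%)`, `CLp 0.01894 mL/h (CV 2.5%)`,
`ktp 0.05976 1/h (CV 6.6%)` against generating values 1.74, 0.0181 and
0.0602 — a single n = 3 study determines the clearance and volumes to a
few percent, while σ₂ is the least identifiable (CV ~33%), as expected
for a convection parameter seen only through slow tissue uptake.

A command-line layer wraps the same calls
(`fusionpk simulate|synth|fit|nca|qc|reproduce`); `fusionpk reproduce
--outdir out --seed 1` runs the whole pipeline (generate → fit → NCA →
assay comparison) and writes CSV reports with a provenance block.

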