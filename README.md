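# cinelv

Cine-MRI left-ventricle quantification and post-infarction remodelling
prediction for the mouse LAD-ligation model.

After permanent ligation of the left anterior descending coronary artery,
the mouse left ventricle dilates, hypertrophies and loses function over the
following weeks (adverse remodelling). Serial short-axis cine MRI tracks
this process, and an early measurement that predicts the late outcome lets
pre-clinical studies stratify animals instead of comparing noisy group
means. `cinelv` implements the full measurement-and-prediction chain for
users analysing manually traced short-axis contour stacks:

* **Volumetry** — per slice and cardiac phase, cavity and myocardial areas
  from traced epicardial/endocardial polygons; slice-summation (Simpson)
  volumes `V = Σ A·h`; global end-diastole/end-systole detection;
  `SV = EDV − ESV`, `EF% = SV/EDV × 100`; LV mass = myocardial volume ×
  1.05 mg/mm³, reported as the mean of the ED- and ES-derived values.
* **Infarct sizing** — mature scar is thinned and akinetic; its extent is
  `IS% = (1/N_slices) Σ ½(I_epi/T_epi + I_endo/T_endo) × 100`, where `I` is
  the marked akinetic arc length and `T` the border circumference at
  end-diastole.
* **Quality control** — ED/ES mass agreement (≤ 5% discrepancy), Bland–
  Altman inter-observer agreement, and correlation of MRI-derived mass
  against autopsy mass.
* **Remodelling prediction** — univariate Pearson correlations of every
  week-1 predictor (LV mass, EDV, ESV, EF, infarct size) against every
  week-4 outcome, simple OLS regression (the headline relation is
  `LV-EDV_wk4 = 1.33·LV-ESV_wk1 + 26 μl`), and stepwise forward selection
  with a partial-F entry test.
* **Synthetic data** — a truncated-ellipsoid cine phantom with analytic
  ground truth (optionally carrying a thinned, akinetic infarct wedge) and
  a cohort simulator with known linear remodelling structure, used to
  validate every stage end to end.

## Worked example

```python
from cinelv import (PhantomSpec, CohortSpec, generate_phantom,
                    generate_cohort, quantify, ols_fit, stepwise_forward)

study, truth = generate_phantom(PhantomSpec())   # 7 x 1 mm slices, 20 phases
res = quantify(study)
print(f"EDV {res.edv:.2f} ul  ESV {res.esv:.2f} ul  EF {res.ef:.2f}%  "
      f"mass {res.mass_avg:.2f} mg  (ES phase {res.es_phase})")
# EDV 64.77 ul  ESV 25.91 ul  EF 59.99%  mass 97.43 mg  (ES phase 8)

cohort, _ = generate_cohort(CohortSpec(seed=7))  # 25 MI + 11 sham animals
fit = ols_fit(cohort, "lv_edv_wk4", "lv_esv_wk1")
print(f"slope {fit.slope:.3f}  intercept {fit.intercept:.2f}  r2 {fit.r_squared:.3f}")
# slope 1.264  intercept 28.14  r2 0.978

print(stepwise_forward(cohort, "lv_edv_wk4").selected)
# ['lv_esv_wk1']
```

The phantom's analytic (quadrature) truth is EDV 64.65 μl / EF 59.99%, so
the traced measurement is within 0.2% — the residual is slice and polygon
discretisation. The simulated cohort is generated with week-4 EDV linear in
week-1 ESV (slope 1.33, intercept 26 μl, plus noise); the fitted line
recovers it up to sampling error, and forward selection identifies week-1
ESV as the sole useful predictor of week-4 dilatation.

A CLI wraps the same pipeline:

```bash
cinelv simulate --kind phantom --out out/           # contour CSV + truth JSON
cinelv quantify out/phantom_contours.csv --out out/ # volumetry, infarct, QC
cinelv simulate --kind cohort --out out/ --seed 7
cinelv predict out/cohort.csv --out out/            # correlations, fits, stepwise
```

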