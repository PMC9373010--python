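# splquant

Quantitative PET/MRI analysis of solitary pulmonary lesions (SPLs): diffusion
model fitting, PET metabolic metrics, and the complete diagnostic-statistics
chain used to judge whether an imaging biomarker separates benign from
malignant lesions and predicts histopathological grade.

It is written for imaging scientists who have (a) multi-b-value diffusion
volumes and lesion ROIs, (b) PET SUV volumes, and/or (c) a per-patient cohort
table of imaging parameters and pathology labels, and who want the familiar
four-table study output — reader agreement, group comparisons, logistic
screening, ROC performance — from reproducible, tested code. Because patient
images from such studies are rarely shared, the package also ships synthetic
generators (diffusion phantoms, PET phantoms, two-reader cohorts) with known
ground truth so every stage can be exercised and validated end to end.

## Models and statistics

**Diffusion.** Signal relative to the unweighted baseline S₀ follows either
the mono-exponential model, fitted in closed form from two b-values
(0, 1000 s/mm²),

    S(b)/S₀ = exp(−b·ADC)

or the diffusion-kurtosis model over four b-values (0, 500, 1000, 2000 s/mm²),

    S(b)/S₀ = exp(−b·D_app + (1/6)·b²·D_app²·K_app)

fitted by nonlinear least squares on the signal domain with a log-domain
quadratic initialisation. D_app (mm²/s) is the non-Gaussian-corrected
diffusivity and K_app the apparent kurtosis; for trace-weighted acquisitions
the mean diffusivity/kurtosis maps are MD ≡ D_app and MK ≡ K_app per voxel.

**PET.** SUVmax is the lesion's highest SUV; MTV (mL) sums the volume of all
ROI voxels with SUV above 40% of SUVmax (strict inequality, no
connected-component filtering); TLG (g) = MTV × mean SUV of the included
voxels.

**Statistics.** Two-reader agreement via ICC(2,1) (two-way random effects,
absolute agreement) with the standard excellent/good/fair/poor categories;
Shapiro–Wilk-gated Student t or Mann–Whitney U group comparisons; empirical
ROC with DeLong-variance confidence intervals and the Youden-index
(sens + spec − 1) optimal cutoff; the DeLong test for paired AUCs; and a
univariate → multivariate logistic screen (selection at p < 0.1) whose
predicted probability acts as the combined diagnostic score. All tests are
two-sided; no multiplicity correction is applied.

## Worked example

```python
import numpy as np
from splquant import (BValueProtocol, DiffusionSignalSeries,
                      DiffusionKurtosisModel, dki_signal)

protocol = BValueProtocol.dki_default()          # b = 0, 500, 1000, 2000 s/mm²
series = DiffusionSignalSeries(
    dki_signal(protocol.as_array(), 1000.0, 1.2e-3, 0.9))
print(np.round(series.as_array(), 1))
print(DiffusionKurtosisModel(series, protocol).fit().summary())
```

prints

```
[1000.   579.3  373.8  215.2]
Diffusion kurtosis fit
----------------------
Dapp          1.200000e-03 mm^2/s
Kapp          0.900000
S0            1000
status        ok
residual norm 0.000e+00
```

— the four decaying signal magnitudes generated at D_app = 1.2×10⁻³ mm²/s and
K_app = 0.9, recovered exactly by the fitter. A full synthetic study runs in
a few lines:

```python
from splquant import CohortSpec, make_cohort, run_study, StudyConfig
cohort = make_cohort(CohortSpec(include_excluded=True, seed=7))
report = run_study(cohort, StudyConfig(seed=7))
print(report.summary())
```

which begins

```
Cohort study report: 73 retained of 121 screened (excluded per flag:
{'no_histopathology': 13, 'solid_component_lt_10mm': 11,
 'multiple_lesions': 15, 'poor_image_quality': 9})

Inter-reader agreement (ICC)
parameter    icc  category
      adc  0.858 excellent
       md 0.8903 excellent
       mk 0.9065 excellent
...
```

i.e. the screening cascade keeps 73 of 121 simulated patients, and the two
simulated readers agree at ICC ≈ 0.86–0.91 on the hand-measured diffusion
parameters, followed by the group-comparison, logistic, ROC and DeLong
tables.

The same pipeline is available from a shell:

```bash
splquant simulate cohort --seed 7 --out cohort_dir
splquant analyze-cohort --cohort cohort_dir/cohort.csv --out report_dir
splquant simulate diffusion --seed 1 --out phantom
splquant fit-dki --dwi phantom/dwi.nii.gz --bvals phantom/bvalues.json --out maps
```

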