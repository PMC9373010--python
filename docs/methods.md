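# Methods

## Diffusion signal models

Both models describe the magnitude signal S(b) of a diffusion-weighted
acquisition relative to its unweighted baseline S₀ = S(0).

The **two-point ADC** uses the mono-exponential (Gaussian diffusion) model
S(b)/S₀ = exp(−b·ADC) and is solved in closed form from the b = 0 and
b = 1000 s/mm² signals: ADC = ln(S₀/S(b₁))/b₁. When S(b₁) ≥ S₀ there is no
measurable decay; the estimate is clipped to 0 and flagged
(`clipped_at_zero`) rather than reported negative. S(b₁) = 0 is a fit
failure.

The **kurtosis model** S(b)/S₀ = exp(−b·D_app + (1/6)·b²·D_app²·K_app)
captures non-Gaussian diffusion through the apparent kurtosis K_app. It is
fitted over b = 0, 500, 1000, 2000 s/mm² by bounded nonlinear least squares
*on the signal domain* — a log-domain objective would distort the
(approximately additive) noise at low SNR — with the starting point obtained
from the unweighted log-quadratic solve ln S = a₀ + a₁b + a₂b², D_app = −a₁,
K_app = 6a₂/D_app². Parameter boxes default to D_app ∈ (10⁻⁶, 10⁻²) mm²/s
and K_app ∈ [0, 3]; these are physiological-plausibility guards, and
solutions landing on a bound are reported with `fit_status =
'clipped_at_bound'` rather than discarded. A flat signal series leaves K_app
unidentifiable (the D_app → 0 branch) and is reported as `failed` with NaN
parameters. Because the quadratic exponent is non-monotone with minimum at
b\* = 3/(D_app·K_app), fits where b\* falls inside the acquired b-range carry
`nonmonotone_warning` — the standard validity caveat of the kurtosis
expansion.

Voxelwise maps treat the acquisition as trace-weighted single-"direction"
data, so MD ≡ D_app and MK ≡ K_app per voxel; multi-direction stacks can be
handled by fitting each direction and averaging the per-direction maps, but
no gradient table handling is built in. Voxels with any nonpositive signal
are excluded from the output mask (the log initialisation is undefined
there); masking is preferred to clamping so that downstream ROI statistics
only see genuinely fitted voxels. ROI values are arithmetic means over ROI
voxels, and the per-lesion analysis value is the mean of the two readers'
ROI means.

## PET metabolic metrics

SUVmax is the maximum SUV inside the lesion ROI. MTV counts ROI voxels with
SUV **strictly greater than** 0.40·SUVmax and multiplies by the voxel volume
(reported in mL); the strict inequality follows the "all voxels larger than
the threshold" convention, and an `inclusive` flag documents the boundary
ambiguity. No connected-component filtering is applied: disjoint hot islands
inside the ROI all count. TLG = MTV × mean SUV of the included voxels, so
TLG = MTV × SUVmean_included holds as an exact identity and
SUVmean_included ∈ [0.4·SUVmax, SUVmax]. MTV is reported in mL and TLG in g
(SUV·mL), the field-standard units; SUV computation from raw activity, dose
and body weight is out of scope — inputs are already SUV images.

## Diagnostic statistics

**ICC.** Inter-reader reliability uses ICC(2,1): two-way random effects,
absolute agreement, single measurement, computed from the two-way ANOVA
table. Absolute agreement is the right form when two fixed readers rate
every lesion and the question is interchangeability of their raw values — a
systematic offset between readers *should* lower the coefficient. A
consistency variant (ICC(3,1)) is available as a config option. Categories:
≥ 0.75 excellent, 0.60–0.75 good, 0.40–0.60 fair, < 0.40 poor.

**Group tests.** Each group is screened with Shapiro–Wilk at α = 0.05; both
normal → Student's t (pooled variance; Welch by flag), otherwise
Mann–Whitney U, two-sided either way, with the branch recorded per
parameter. The gate can be overridden per parameter to pin a published test
assignment.

**ROC.** The empirical AUC is the Mann–Whitney probability with ties counted
half, computed via midranks. Marker direction is auto-oriented so AUC ≥ 0.5
and recorded. The 95% CI uses the DeLong placement-value variance. The
optimal cutoff maximises the Youden index over observed score values;
Youden ties break toward the cutoff with higher specificity (then the more
extreme cutoff), which makes reporting deterministic.

**DeLong test.** Paired AUCs are compared through the covariance of their
placement values, with a two-sided normal test on the AUC difference. A
degenerate (zero) variance — identical or perfectly rank-correlated
markers — is flagged and reported as p = 1. In the pipeline each marker is
oriented toward its positive direction before comparison, so the test
addresses the reported (≥ 0.5) AUCs, matching how ROC packages pair curves.

**Logistic screen.** Each candidate is fitted alone against the binary
outcome (maximum-likelihood logistic regression; odds ratio per unit with
95% Wald CI); candidates at univariate p < 0.1 enter one multivariate model
whose predicted probability is the combined score, itself analysable as a
ROC marker. Perfect separation (detected by non-convergence or exploding
standard errors) flags the candidate and keeps it out of the multivariate
fit. No multiple-testing correction is applied anywhere, and the report
carries a note saying so.

## Study pipeline

Screening applies the exclusion flags (no histopathology, solid component
< 10 mm, multiple lesions, poor image quality); a record with several flags
is excluded once but appears in every flag's tally. With the default
generator counts (13/11/15/9 disjoint flags on 121 screened) retention is
exactly 73. Grade grouping: grade 3 → high-grade, grades 1–2 →
non-high-grade, with small cell carcinoma treated as grade 3 and bronchial
adenoma as grade 1; benign lesions get no grade group. The full run chains
reader averaging → ICC → group comparisons for both contrasts → logistic
screen (candidates: age, sex, smoking, diameter and the six imaging
parameters) → per-parameter and combined-score ROC → DeLong comparisons of
the combined score against each parameter, and serialises everything to
JSON + CSV. Reports are byte-identical under a fixed cohort and config; the
report's Youden identity and selection-containment invariants are asserted
on every run.

## Synthetic data: what it emulates, and what it does not

**Diffusion phantoms** are two-region grids (spherical "lesion" in a
background) whose noiseless signals satisfy the kurtosis equation at machine
precision. Noise is Gaussian or Rician (default Rician — magnitude MR data —
with σ = S₀/SNR), the latter reproducing the noise-floor bias that drags
high-b signals, hence ADC, as SNR falls. Defaults (16³ grid, 2 mm voxels,
lesion D_app = 1.2×10⁻³ mm²/s / K_app = 0.9 against background
2.5×10⁻³ / 0.4, SNR 50) represent a restricted-diffusion lesion on lung-like
background at clinically plausible SNR.

**PET phantoms** assign explicit SUVs to lesion voxels over a uniform
background, so SUVmax/MTV/TLG ground truth is computable by direct
enumeration; plateaus and gradients make the 40% isocontour nontrivial.

**Cohorts** draw each patient's six imaging parameters from per-stratum
Gaussians. Strata are benign (n = 15) and the two malignant grade strata
(high-grade n = 31, non-high-grade n = 27; malignant total 58, sized to be
consistent with the published sensitivity/specificity fractions, e.g.
79.31% = 46/58). Malignant patients are generated from the grade-specific
statistics, so the pooled malignant group is the implied mixture — for MD,
MK and SUVmax this pooling reproduces the published pooled cells almost
exactly, which is why grade-conditional generation was chosen as the
coherent single-table model; the source's pooled ADC and MTV cells are
inconsistent with their own grade cells and are kept as comments in the
defaults rather than silently corrected. Covariates: age N(60.0, 10.41²),
male fraction 53/73, lesion diameter N(3.68, 1.77²) cm, smoking prevalence
0.45 (not reported in the source; chosen as a realistic value for a
suspected-lung-malignancy cohort). Two reader columns add independent
homoscedastic Gaussian noise to the true diffusion-parameter values; the
default SDs (ADC 0.15, MD 0.19, MK 0.05, in reporting units) are sized so
the generated ICCs sit near the reported inter-reader agreement
(0.836/0.897/0.867). Negative draws of nonnegative quantities are floored
at 10⁻⁶ rather than redrawn, keeping random streams aligned when a single
parameter changes. All generators are bit-reproducible given (spec, seed).

Deliberately **not** emulated: lung anatomy, respiratory motion, EPI
distortion, partial-volume effects, between-parameter correlations within a
patient, and any coupling between covariates and imaging parameters (each
cohort column is drawn independently given the stratum). Passing tests
therefore demonstrate correctness of the estimators and statistics under
the stated generative model, not robustness to real-world acquisition
artefacts.

## Numerical choices and problem sizes

Optimiser tolerances are set tight (xtol = ftol = gtol = 10⁻¹⁴) so noiseless
round trips recover parameters to ≤ 10⁻⁶ relative error. Phantom grids in
the tests are 4³–16³ and the Monte-Carlo fit study uses 1000 replicate
series at SNR 50; the cohort-limit checks use 10⁵-draw strata for moment
convergence and 10⁶ per group for the binormal AUC limit, sizes at which the
Monte-Carlo error (≈ 4×10⁻⁴ on the AUC) sits well inside the 0.002
tolerance while the whole suite stays fast on a single CPU.

## Known limitations

- Single-direction (trace-weighted) DKI only; no gradient-table support.
- The logistic screen assumes complete cases and numeric/binary-codable
  covariates; no regularisation, so small-sample multivariate odds ratios
  can be unstable (exactly as in the classical analysis it mirrors).
- The Youden cutoff is evaluated at observed marker values, not midpoints
  between them (a midpoint option would shift cutoffs, never the index).
- MTV/TLG units assume isotropically scaled voxel volumes supplied by the
  caller; DICOM/PACS ingestion, registration and attenuation correction are
  out of scope.
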