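# Methods

## Signal model and tensor estimation

Diffusion-weighted signals follow the monoexponential tensor model
S = S₀ exp(−b gᵀDg) with D a symmetric 3×3 tensor (mm²/s). The
estimator is plain (unweighted) least squares on the log signal,

ln S = ln S₀ − [b gx², b gy², b gz², 2b gx gy, 2b gx gz, 2b gy gz]·d,

solved once per volume as a multi-right-hand-side least-squares problem.
This is the canonical baseline estimator: deterministic, exact on
noiseless data (the acceptance suite verifies recovery of all six
components to better than 1e-9 relative error), and adequate for the
single-shell 20-direction, b = 1000 s/mm² protocol emulated here.
Weighted or iterative estimators would reduce noise-induced variance at
low SNR but introduce estimator-specific behaviour we cannot anchor to a
reference; the external toolboxes commonly used for this computation do
not document their default beyond least squares.

Multiple b=0 volumes are averaged before fitting. Voxels containing any
non-positive signal are flagged as background and excluded. If the
direction set cannot identify all six tensor unknowns the fit aborts and
names the unidentifiable components (from the design null space).
Negative eigenvalues are clamped at zero **only** for FA and colour-FA;
the diagonal entries Dxx/Dyy/Dzz that feed the ALPS index are kept as
fitted, because the index is defined on raw axis diffusivities and
clamping would bias low-SNR ratios.

## ALPS index and ROI handling

ALPS = mean(Dxx over the projection-fiber ROI, Dxx over the
association-fiber ROI) / mean(Dyy over the projection ROI, Dzz over the
association ROI). ROIs are spheres (default diameter 5 mm) specified by
world-mm centers; membership is voxel-center distance ≤ radius with ties
included, and ROI means are unweighted voxel averages. Centers are
supplied manually (in the source study they are placed by eye on the
colour-FA map in the left hemisphere); `suggest_roi_center` can propose
a center by maximising the orientation-QC score on a chosen axial slice
but never overrides manual coordinates. Orientation QC checks that at
least `min_fraction` (default 0.5) of ROI voxels have FA ≥ `min_fa`
(default 0.2) with the principal eigenvector dominant on the expected
axis (projection → z, association → y). A subcortical-fiber ROI, where
placed, is QC-only and never enters the index. Measurement is
single-sided (left hemisphere) by convention; nothing in the code is
hemisphere-specific beyond the supplied centers.

World space is RAS with x = right–left, the axis along which the
perivascular spaces run at the ventricle-body level; b-vectors are
interpreted in world axes after reorientation. The index is invariant
to any positive rescaling of the diffusivity maps and equals 1 exactly
on isotropic data, both verified by tests.

## Clinical encodings

Markers are visual ratings entered as data, not image segmentations:
Fazekas grades 0–3 per region summed to 0–6 (the study population spans
3–6); lacune and CMB totals as non-negative counts; PVS grades 0–4 from
the worst-slice count (0, 1–10, 11–20, 21–40, >40), with "moderate to
severe" meaning a grade strictly above 2 in either region (the literal
reading of the published rule; the alternative ≥2 convention exists but
is not used). Cognitive impairment is MoCA ≤ 13 / 19 / 24 for 0 / 1–6 /
≥7 years of education. Eligibility requires at least one region with
Fazekas ≥ 2 (our reading of "Fazekas 2–3 WMLs", consistent with a
minimum observed sum of 3), one additional marker, and age 50–80.

## Statistical battery

Two-sided tests and 95% intervals throughout; no multiplicity
correction (none is used in the design being reproduced). Missing
values are deleted listwise per model and every fit reports its n.

* **Mann–Whitney U** with midrank ties; exact null distribution when
  min(n) ≤ 8 and the data are untied (verified against full enumeration
  for all layouts with n₁,n₂ ≤ 6), tie-corrected continuity-corrected
  normal approximation otherwise.
* **Chi-square** (Pearson); Yates continuity correction applied
  automatically to 2×2 tables with any expected count below 5.
* **Logistic regression** by maximum likelihood (Newton; BFGS fallback
  when quasi-separation makes the Hessian singular). Odds ratios are
  exp(B) with Wald intervals exp(B ± 1.96·SE). Perfect separation and
  divergent fits raise an explicit error rather than returning silently
  divergent coefficients; rank-deficient designs raise an error naming
  the collinear terms.
* **Backward stepwise elimination** starts from the full model and
  repeatedly removes the term with the largest single-term
  likelihood-ratio p-value above `alpha_remove` (default 0.10, the
  default of the commercial package used in the original analysis;
  both criterion and threshold are arguments because the original
  report does not state them). Listwise deletion happens once on the
  full candidate set so every step sees the same cases. The final model
  matches a subset-enumeration oracle (all 2^k candidate subsets fitted
  by an independent optimiser, removal rule replayed by lookup) on
  every seeded test problem.
* **ROC/AUROC**: empirical curve over all thresholds, trapezoidal AUC,
  ties by simultaneous crossing (equivalent to counting tied pairs ½ —
  hence AUC ≡ U/(n₁n₂), which the tests assert to 1e-12). Score
  direction is explicit; `auto` picks the orientation with AUC ≥ 0.5
  and records it (for the ALPS index, lower values flag impairment).
  Single predictors are scored raw; the combined model uses the fitted
  logistic probability. AUROCs are apparent (training-sample) values,
  matching the original design; cross-validated variants are out of
  scope.
* **Linear models**: OLS with t-based intervals; VIF_j = 1/(1−R²_j)
  from regressing predictor j on the others, reported per predictor and
  infinite (with an error) under exact collinearity. The vascular
  adjustment set is age, education, hypertension, diabetes, smoking,
  alcohol abuse; the imaging set is WML sum, lacunes, moderate-severe
  PVS, CMBs.

## Synthetic ground truth

**Phantoms.** A 32×32×12 grid at 1.75×1.75×2.4 mm holds a z-dominant
projection slab, a y-dominant association slab, an isotropic CSF-like
block (3.0×10⁻³ mm²/s) and isotropic background (0.8×10⁻³). Default
fiber eigenvalues are (0.4, 0.4, 1.4)×10⁻³ with a perivascular x-axis
increment δ = 0.2×10⁻³ added in both fiber slabs, giving an analytic
ALPS of 1.5 computable without simulation. The acquisition is one b=0
plus a frozen 20-direction electrostatic-repulsion scheme at b = 1000
(the scanner's actual direction table is unknown; a fixed versioned set
keeps every run reproducible). Rician noise is the magnitude of a
complex Gaussian perturbation with σ = S₀/SNR. The phantom has no
anatomy, partial-volume mixing, motion or eddy effects, so phantom
tests validate the numerics of fit → maps → ROI → index, not robustness
to real-world artefacts.

**Cohorts.** Two latent groups (50 + 83) carry the observed
case–control structure: ALPS ~ N(1.054, 0.142²) vs N(0.958, 0.088²);
WML-sum categories 3–6 with the observed per-group frequencies
(decomposed uniformly into per-region grades honouring the eligibility
rule); lacune and CMB counts negative-binomial matched to the observed
mean/SD; PVS grades tuned so the moderate-severe prevalence matches
(~0.87); ages, education and risk-factor prevalences from the observed
summaries, with a 5% missingness rate on the risk booleans (the
published denominators imply missing risk data; 5% keeps per-model n
near the cohort size). Cognitive scores are linear in the ALPS index,
education and WML sum with coefficient magnitudes on the scale of the
adjusted regression tables (e.g. 16.094 MoCA points per unit ALPS,
0.683 per education year, −1.577 per WML grade) plus Gaussian residuals
chosen so total SDs land near the observed ones. Marker draws are
independent across marker families (their true covariance is unknown);
couplings are config-exposed.

The CN/CI label is **assigned by the education-adjusted MoCA cutoff
applied to the generated MoCA**, never drawn directly, so the
classification rule is exercised and borderline subjects cross over
exactly as the rule dictates. Group MoCA bases (26.5/15.5) were chosen
once so the assigned groups track the latent ones closely; because
label crossovers correlate with the ALPS index (MoCA is coupled to it),
the assigned-group effect sizes run somewhat stronger than the observed
ones — synthetic single-predictor AUROCs average ≈0.78 for ALPS versus
the reported 0.694. Replicate-level conclusions (which terms survive
elimination, ordering of AUROCs) are the quantities the generator is
designed to probe; its absolute effect sizes are not calibrated to the
clinical data and passing tests do not certify behaviour on real
cohorts.

## Numerical choices and edge cases

* Sphere membership includes boundary ties; voxel indexing is 0-based.
* The all-zero tensor has FA defined as 0 (not NaN); principal
  eigenvectors carry a canonical sign (largest-magnitude component
  positive) for reproducibility.
* An ALPS denominator ≤ 0 (non-physical fiber-perpendicular
  diffusivity) is an error, not a NaN.
* Stepwise with `alpha_remove = 1` returns the full model; an empty
  (intercept-only) final model is legal.
* At n ≈ 133 an indicator with ~0.87 prevalence occasionally
  quasi-separates the outcome in simulation; the fit then raises an
  explicit separation error and replicate studies record that replicate
  as failed rather than forcing a model.
* Problem sizes in tests and the acceptance script (32×32×12 phantoms,
  100–200 replicate cohorts, n = 150 stepwise-oracle problems) were
  chosen so each stage still exercises the full code path while the
  whole suite completes in a few minutes on one CPU.

## Known limitations

No eddy/motion/denoising preprocessing is implemented (none is
described in the emulated protocol); DICOM ingestion, atlas-based ROI
registration, the modified ALPS variant, multi-shell models and lesion
segmentation are out of scope. The bvec frame is assumed already
world-aligned. Apparent AUROC overstates out-of-sample discrimination;
the package reports it because the reproduced design does.
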