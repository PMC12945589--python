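# strainmap

Normative shear-strain vulnerability mapping from brain MR elastography
(MRE), and strain-stratified diffusion-MRI statistics for mild traumatic
brain injury (mTBI).

The scientific question: does the healthy brain concentrate mechanical
shear strain in stereotyped locations, and do exactly those locations show
reduced tissue integrity after concussion? `strainmap` implements the full
analysis chain for researchers working at the intersection of brain
biomechanics and diffusion imaging:

1. **Strain metrics** — octahedral shear strain
   OSS = (2/3)·√[(ε₁−ε₂)² + (ε₂−ε₃)² + (ε₃−ε₁)²] and maximum principal
   strain ε₁ from voxelwise strain tensors; damping ratio ξ = G″/(2G′)
   from viscoelastic moduli; within-subject z-scoring and normative
   (cohort-mean) maps.
2. **Vulnerability map** — voxelwise one-sample t-tests on OSS z-maps,
   Benjamini–Hochberg FDR over the brain mask, and a joint threshold
   (q < 0.05 and t ≥ 4) defining high-strain (HS) vs low-strain (LS)
   regions, with leave-one-out cross-validation (Wilcoxon matched pairs)
   and tissue-composition summaries.
3. **Apparent fiber density** — single-shell constrained spherical
   deconvolution: weighted tensor fit, response calibration from high-FA
   voxels, iterative non-negativity-constrained fODF recovery in a real
   orthonormal SH basis, and AFDtotal = the l = 0 fODF coefficient.
4. **Group statistics** — subject-level mean AFD in 0.25-z bins of the
   normative OSS map; the mixed model
   `AFD_mean ~ group × OSS_bin_center + (1 | subject)` exposed
   statsmodels-style as `StrainAFDModel` → `StrainAFDResults.summary()`;
   ΔAFD curves with CIs; 2×2 mixed ANOVAs, directed Welch tests on
   AFD_HS/AFD_LS ratios, and sex-stratified contrasts.
5. **Synthetic cohorts** — a generator that plants known vulnerable
   regions, modulus contrasts and group-specific AFD–strain slopes, so the
   whole pipeline is testable end to end without access to MRE depositions
   or clinical data.

See `docs/methods.md` for the model, its assumptions, and every default.

## Worked example

Run the end-to-end synthetic study (20-subject MRE cohort with
leave-one-out validation, then a 15 + 15 diffusion cohort generated with
the subacute/chronic slope preset):

```python
from strainmap.config import PipelineConfig
from strainmap.pipeline import run_pipeline

cfg = PipelineConfig(output_dir="demo_out", seed=7, n_mre_subjects=20,
                     n_control=15, n_mtbi=15, preset="subacute_chronic",
                     run_loo=True)
stats = run_pipeline(cfg)
```

`demo_out/` then contains the normative OSS z-map, HS/LS masks, per-bin
tables, figures and a provenance record, and `demo_out/lme_summary.txt`
prints:

```
Strain-stratified AFD mixed model (random intercept per subject)
  method: reml   subjects: 30   obs: 390
  random-intercept variance: 0.000916932
  term            estimate        2.5%       97.5%         p
  intercept        0.61946     0.60390     0.63502         0
  group           -0.05122    -0.07323    -0.02922  5.05e-06
  oss              0.04419     0.04275     0.04563         0
  interaction     -0.01248    -0.01451    -0.01045  2.71e-33
  slope_control: 0.04419   slope_mtbi: 0.03171
```

Reading this: AFD rises with normative strain in both groups (`oss` is the
control slope, 0.044 AFD per z), but ~0.012 AFD/z *less steeply* in the
mTBI group (the negative `interaction`; the generative slopes were 0.041
vs 0.029). The fitted slopes sit slightly above the generative values
because this demo estimates the normative map from a finite, noisy
20-subject MRE cohort, which mildly compresses the z-axis. The
accompanying `statistics.json` reports, from the same run: a significant
2×2 group-by-region interaction (F = 56.7), a directed AFD_HS/AFD_LS ratio
deficit in mTBI (Welch t = 4.48, one-sided p = 6.9e-05), every
leave-one-out fold showing higher held-out strain in HS than LS (Wilcoxon
p = 1.9e-06), and the planted mechanical structure — higher storage
modulus (paired t = 18.1) and lower damping ratio (t = −14.0) in
high-strain tissue.

The same stages are scriptable from the shell:

```bash
strainmap simulate --n-subjects 10 --seed 1 --output-dir sim/
strainmap oss sim/strain_tensor_000.nii.gz --mask sim/brain_mask.nii.gz \
    --zscore --output z000.nii.gz
strainmap mask z*.nii.gz --mask sim/brain_mask.nii.gz --output-dir roi/
strainmap run --seed 7 --output-dir demo_out
```

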