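# Methods

`strainmap` implements a normative-strain vulnerability analysis for mild
traumatic brain injury (mTBI): it maps where the healthy brain concentrates
octahedral shear strain (OSS) under external skull actuation, defines
high-strain (HS) regions from cohort statistics, computes apparent fiber
density (AFD) from single-shell diffusion MRI, and tests whether normative
strain concentration predicts group differences in AFD. Because the public
MRE depositions and clinical cohorts behind the original analysis are not
redistributable, the package ships a synthetic-cohort generator with known
ground truth; every statistical claim the test suite makes is a claim about
recovery of that ground truth, not about real brains.

## Strain metrics

Each voxel carries a symmetric Green–Lagrange strain tensor ε with
eigenvalues ε₁ ≥ ε₂ ≥ ε₃. The package computes

- **OSS** (octahedral shear strain):
  γ_oct = (2/3)·√[(ε₁−ε₂)² + (ε₂−ε₃)² + (ε₃−ε₁)²] — a rotation-invariant
  summary of the shear part of the deformation, insensitive to the
  hydrostatic component (adding c·I changes nothing).
- **MPS** (maximum principal strain): ε₁, which mixes shear and
  longitudinal strain.
- **Damping ratio** ξ = G″/(2G′) from the storage (G′) and loss (G″)
  moduli, a dimensionless measure of relative energy dissipation. The
  denominator is taken as 2G′ (the standard definition consistent with
  G* = G′ + iG″); this is configurable nowhere because no analysis in the
  package depends on the overall ξ scale, only on HS-vs-LS contrasts.

Eigenvalues are computed per voxel with `numpy.linalg.eigvalsh` on the
reassembled 3×3; ties are allowed and ordering is by sort.

Per subject, OSS is z-scored across all in-mask voxels (sample, n−1
denominator), and the normative map is the voxelwise mean of the
within-subject z-maps. The alternative order (average raw OSS maps, then
z-score the mean) is available through the pipeline configuration
(`zscore_before_average: false`); z-scoring first is the default because
it makes subjects with different overall strain magnitude commensurate,
which is the point of the normalization.

## High-strain region definition

A voxelwise one-sample t-test across subjects (H₀: mean OSS z = 0,
df = n−1, two-sided p) feeds Benjamini–Hochberg step-up FDR computed over
in-mask voxels only. The HS region is the joint set {q < 0.05 and t ≥ 4};
LS is its complement within the brain mask, so HS and LS always partition
the mask (asserted on construction). Zero-variance voxels are retained with
t = 0, p = 1 so the BH multiplicity count m is reproducible. The t ≥ 4
gate enforces positivity, so the sidedness of p only affects the FDR
denominator; two-sided is the default. No cluster-extent filtering or
smoothing is applied by default (`min_cluster_size = 1`).

Generalizability is assessed by leave-one-out cross-validation: the mask is
rebuilt from n−1 subjects, the held-out subject's mean OSS inside HS and LS
is recorded, and a Wilcoxon matched-pairs signed-rank test (zeros dropped;
exact p for ≤ 25 pairs, normal approximation with continuity correction
above) compares the paired fold values.

## AFD from single-shell diffusion MRI

The diffusion arm follows the standard single-tissue CSD recipe:

1. **Tensor fit**: weighted log-linear least squares (one reweighting pass
   with weights = squared predicted signal); FA and MD from eigenvalues,
   negative eigenvalues clamped to zero for FA with a counter.
2. **Response calibration**: voxels with FA ≥ 0.7 (up to 300, highest FA
   first; ≥ 20 required) are reoriented so the principal eigenvector sits at
   the pole, and the pooled b0-normalized signals are projected onto the
   m = 0 even spherical harmonics up to l_max.
3. **CSD**: the fODF is recovered in a real, orthonormal, even-order SH
   basis (identifier `real_sym_orthonormal`) by deconvolving the signal
   with the response via the Funk–Hecke weights
   √(4π/(2l+1))·r_l, under an iterative soft non-negativity constraint:
   amplitudes on a fixed 300-direction Fibonacci sphere falling below
   τ·(mean initial amplitude), τ = 0.1, are penalized with weight λ = 1
   (scaled by the Frobenius-norm ratio of the data and constraint
   operators) until the constraint set stops changing (max 50 iterations;
   non-convergent voxels are kept and counted). l_max defaults to 8 and is
   lowered automatically when there are fewer directions than coefficients.
4. **AFDtotal** is the l = 0 fODF coefficient c₀₀; in this basis the
   spherical mean of the fODF equals c₀₀/√(4π), and a unit single-fiber
   voxel yields c₀₀ ≈ 1/√(4π). Signals are divided by the mean b0 per
   voxel before deconvolution, which fixes the AFD units across subjects.

The choice of a code-generated Fibonacci direction set (rather than a
stored electrostatic-repulsion set) keeps the package free of data files;
its slight non-uniformity is irrelevant at 300 points. Exact rotational
equivariance of AFD is limited by the fixed constraint sphere: the residual
is ~10⁻⁵ at 300 directions and falls below 10⁻⁶ at ~2400, which the test
suite verifies.

## Group statistics

The normative OSS z-map is discretized into bins of width 0.25 z (edges
anchored at integer multiples of the width; half-open intervals with a
closed top edge). For each subject the mean AFD per bin (bins with < 10
voxels dropped) forms the subject-by-bin table — the unit of analysis is
the subject, never the voxel. On this table:

- **ΔAFD curve**: per-bin control−mTBI mean difference with a
  pooled-variance two-sample t interval.
- **Mixed model** (`StrainAFDModel`): mean_afd ~ group × OSS_bin_center
  with a random intercept per subject, fitted by REML (statsmodels
  `MixedLM`; ML fallback on convergence failure), Wald 95% CIs. Group is
  treatment-coded (control = 0, mTBI = 1) and the strain covariate is
  centered at its grand mean, so the group coefficient is the group
  difference at mean strain. The results object reports per-group slopes
  and the *slope attenuation* (control − mTBI slope difference), which is
  the sign convention in which the interaction is usually quoted (a
  positive attenuation means AFD rises less steeply with strain in mTBI).
  Singular fits (zero between-subject variance) are flagged but fixed
  effects are still reported; bins are treated as exchangeable repeated
  measures beyond the random intercept.
- **ROI analysis**: per-subject HS mean, LS mean and the ratio
  AFD_HS/AFD_LS; a 2 (group, between) × 2 (region, within) mixed-design
  ANOVA (pingouin) on the region means; a directed Welch two-sample t-test
  on the ratio (default H₁: mTBI lower; equal-variance variant available);
  and the same ratio test repeated within strata (e.g. sex), skipping
  strata with fewer than two valid subjects per group.

## Synthetic study conditions

The generator's defaults are the conditions under which the package's
statistical claims are made:

- **Grid**: 48×56×48 voxels at 2 mm (a desk-scale stand-in for a
  stereotaxic 1 mm template; statistics, not anatomy, are the target), with
  an ellipsoidal brain mask (~46k voxels).
- **Normative field**: baseline 1.0 (arbitrary strain units) + a smooth
  background (Gaussian random field, 6 mm correlation length, sd 0.03) +
  three spherical "vulnerable" blobs of radius 12 mm and amplitudes 1.6,
  2.0, 2.4, loosely emulating the handful of deep structures (midbrain-,
  cerebellum-, mesial-temporal-like) that concentrate strain. After
  z-scoring the field spans roughly −0.5 to +4.9 z.
- **MRE subjects**: per-subject OSS = normative + white Gaussian noise
  (sd 0.2 strain units). The strain tensor at each voxel is a fixed unit
  deviatoric template diag(1,0,−1)/γ_oct scaled to the target OSS and
  conjugated by a smoothly varying rotation field, so eigen-analysis
  recovers the planted OSS exactly while the tensor orientations vary
  realistically in space.
- **Moduli**: G′ = 2200 Pa baseline with +300 Pa inside the planted
  region; ξ = 0.25 baseline with −0.05 inside (G″ = 2G′ξ); white noise of
  50 Pa / 0.005 respectively. Each subject scales the planted contrast by
  a factor 1 + N(0, 0.25²), clipped at 0.2 so the planted direction (HS
  stiffer, HS less dissipative) holds for every subject while the paired
  HS-vs-LS t-statistics take realistic rather than astronomically large
  values.
- **AFD subjects**:
  AFD(v,s) = 0.5 + slope_group·z(v) + u_s + η_{s,b(v)} + ε_v with
  u_s ~ N(0, 0.03²) a global subject offset, η_{s,b} ~ N(0, 0.02²) a
  regional (strain-stratum) subject effect, and ε_v ~ N(0, 0.05²) voxel
  noise. The regional term reflects that real subjects deviate from their
  global offset coherently over anatomical territory rather than
  independently per voxel; it is also what makes the subject-by-bin table
  satisfy the exchangeable-residual assumption of the mixed model — with
  iid voxel noise alone, bin-mean residual variance scales as 1/n_voxels
  and the plain LME's Wald test is visibly miscalibrated.
- **Presets** (slopes in AFD units per OSS z): `subacute_chronic`
  (control 0.041, mTBI 0.029), `acute` (control 0.041, mTBI 0.043),
  `null` (0.041, 0.041), `hs_deficit` (equal slopes plus a 0.02 AFD
  decrement confined to the planted region in the mTBI group). Cohort
  sizes used in the recovery experiments: 31 + 31 (subacute/chronic) and
  29 mTBI + 15 controls (acute).
- **DWI**: sum of cylindrically symmetric tensor compartments
  (axial/radial diffusivities 1.7/0.3 ×10⁻³ mm²/s by default) plus an
  isotropic remainder (3.0 ×10⁻³ mm²/s), single shell b = 1000 s/mm² with
  64 Fibonacci-hemisphere directions and one b0; Rician noise at a stated
  SNR. Sex is assigned alternately F/M and enters no generative equation;
  sex-stratified analysis is purely a grouping feature.

What the generator does **not** emulate: brain anatomy and tissue
boundaries, CSF/skull geometry, wave-propagation physics, registration
error, spatially correlated AFD noise beyond the bin-level term, and any
relationship between the DWI arm and the AFD maps (AFD cohorts are drawn
directly from the generative model; the CSD chain is validated separately
on voxel sets). Passing tests therefore demonstrate correctness and
calibration of the *procedures* under known conditions, not effect sizes
in real cohorts.

### Fast generator paths

Large calibration suites (1000-replicate type-I error, 500-replicate
power) use `simulate_binned_afd` and `simulate_roi_summary`, which draw
the subject-by-bin table / region summaries directly from the same
generative model (bin-mean voxel noise = σ_vox/√n_voxels; region means as
exact linear functionals). These are distributionally identical to
volume simulation followed by averaging — the noiseless case matches the
full path to 1e-12 in the tests — and roughly two orders of magnitude
faster. The headline recovery experiments use the full volumetric path.

## Numerical choices and degenerate inputs

- Constant maps cannot be z-scored (error); zero-variance voxels in the
  group t-test are retained as t = 0, p = 1 with a warning counter.
- An empty HS mask raises with advice to review thresholds; empty LOO
  folds are excluded and reported.
- All-zero paired differences give t = 0 by convention; constant non-zero
  differences are a degenerate paired t (error).
- The bin assignment puts a maximum sitting exactly on an edge into the
  bin below (closed top edge); edges are anchored at integer multiples of
  the width for cross-cohort reproducibility.
- Every random draw flows from `numpy.random.default_rng` seeded from the
  call's seed argument; identical (spec, seed) reproduce outputs
  bit-identically, including across the end-to-end pipeline.

## Problem sizes in the shipped experiments

The recovery experiments use 50 replicates, calibration suites 1000
(type-I) and 500 (power) replicates, plant-recovery cohorts 30 subjects,
leave-one-out 20 subjects, null FDR checks 200 cohorts of 30 subjects on a
reduced 24×28×24 grid, and the CSD cross-check 500 voxels — sizes chosen
so the whole suite runs in minutes on a laptop while keeping Monte-Carlo
error well inside the asserted bands.

## Known limitations

- The HS/LS machinery assumes co-registered inputs on one grid; no
  registration is performed or checked beyond affine equality.
- `run_pipeline` drives the synthetic study; real, pre-registered volumes
  are analyzed stage-wise via the CLI subcommands or library calls.
- Single-tissue, single-shell CSD only; AFD is interpreted as an
  amplitude-based contrast, not an intra-axonal volume fraction.
- The mixed model treats bins as exchangeable given the random intercept;
  richer within-subject covariance is out of scope.
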