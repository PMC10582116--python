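# Methods

`motormap` reimplements, as a tested library, the analysis chain used to
compare whole-brain motor-task activation between two groups (in the
motivating study, 33 female and 28 male adults performing 12 movement
conditions over 6 fMRI runs; OpenNeuro ds004044): first-level block-design
GLM, fixed-effects run averaging, TFCE max-statistic permutation inference,
activation-extent and spatial-similarity metrics, pairwise voxel-wise
correlation variability statistics, and structural-metric comparisons.
Because the raw images are not shipped, a synthetic cohort generator
provides ground truth for every stage, and the published summary tables are
used as inputs where the analysis operates on printed numbers.

## Synthetic cohort model

Each condition activates a spherical *footprint* of voxels around a
per-subject center.  The generative model, per subject and condition:

- **center** = group center + isotropic Gaussian jitter with SD
  `center_jitter_sd_vox` (voxels), resampled (then clipped) so the whole
  footprint stays in-grid.  Jitter is the single knob for between-subject
  spatial variability.
- **extent** = all voxels within Euclidean distance `footprint_radius_vox`
  of the center.  Radius is the knob for group differences in activation
  volume.
- **signal**: `baseline * (1 + amplitude/100 * regressor(t))` inside the
  footprint, where the regressor is the block boxcar convolved with the
  double-gamma HRF rescaled to unit integral, so a sustained block plateaus
  at exactly `amplitude` percent signal change.  Default amplitude 1.5 %SC
  on a baseline of 100, a typical motor-block effect size.
- **noise**: i.i.d. Gaussian per voxel-timepoint with SD `noise_sd`
  (default 1, i.e. 1% of baseline).  No temporal autocorrelation, no
  physiological or motion structure — the GLM here does no prewhitening, so
  white noise keeps the simulation and the model consistent.

The block design mirrors the study paradigm: every condition appears
`blocks_per_run_per_condition` times per run (default 2) in a
seed-randomized order, blocks of 16 s separated by short rest gaps, 6 runs
at TR = 2 s at full scale (2 blocks x 16 s x 6 runs = 192 s of task data
per condition).  A condition listed without a footprint entry (e.g.
`rest`) is scheduled and modelled but evokes no signal, giving a
baseline-only contrast.

All subjects share one voxel grid; registration is deliberately not
simulated, which isolates the statistics under test.  Structural metrics
are drawn independently lognormal with moment-matched mean/SD per group;
the default group parameters are reconstructed from the published group
statistics (brain volume directly; per-hemisphere metrics as published
ratio x group-mean brain volume, since only normalized values are
printed).

What passing tests on this generator do *not* show: robustness to
registration error, temporally autocorrelated or physiological noise, head
motion, non-spherical activation geometry, or HRF variability across
subjects.  The generator validates the statistical machinery, not the
acquisition model.

## First-level GLM

The HRF is the canonical double-gamma difference of gamma densities
(shape = delay/dispersion): peak delay 6 s, undershoot delay 16 s,
dispersions 1, undershoot ratio 1/6, rescaled to unit peak and sampled at
0.1 s over a 32-s support.  Only "double-gamma" is fixed by the analysis
being reproduced; these canonical parameters are pinned here so results
are exactly reproducible.

Design matrix: per condition, boxcar on the oversampled grid, convolved
with the kernel, sampled at the TR; a temporal-derivative column (first
difference of the task column divided by the TR, first sample 0, not
orthogonalized) absorbs small latency shifts; plus an intercept.  Per-voxel
OLS gives `beta = (X'X)^-1 X'y`; the per-condition contrast selects the
task column only (derivative as nuisance), so `cope = beta_task`,
`varcope = sigma^2 (X'X)^-1[task,task]`, `t = cope/sqrt(varcope)` with
`dof = T - rank(X)`.  Zero-variance voxels get `t = 0` when the cope is 0
and a signed infinite sentinel otherwise; sentinels are excluded pairwise
from all downstream correlations, and permutation routines cap |t| at 1e6
so TFCE stays finite.

Fixed effects across runs implement the literal "average the parameter
estimates": `cope = mean(run copes)`, `varcope = sum(run varcopes)/K^2`,
`dof = sum(run dofs)` — a deliberate simplification relative to
inverse-variance weighting, appropriate because synthetic runs are
homoscedastic by construction.

## Group inference

TFCE with the established volumetric defaults E = 0.5, H = 2,
26-connectivity, and dh = max/n_steps (n_steps = 100; thresholds are
endpoint-exact so the peak voxel is never lost to float rounding).
Negative values are enhanced separately on the sign-flipped map and
recombined with sign; one-tailed tests use the positive part only.

FWE control is max-statistic permutation: sign-flips of subject maps for
one-sample tests, group-label exchanges for two-sample tests (pooled-
variance t).  When the label space has at most `n_perm` elements it is
enumerated exhaustively and p = count/N; otherwise `n_perm` relabelings
are sampled and the add-one convention `p = (1+count)/(n_perm+1)`
guarantees validity (so p can never reach 0; all ">=" comparisons carry a
1e-12 relative tie tolerance so exact ties are never dropped by float
noise).

## Activation and variability metrics

Activation extent is the count of FWE-significant voxels per group and
condition; the between-group percent difference is
`(count_B - count_A)/count_A * 100`.  Spatial similarity is the demeaned
Pearson correlation, over the shared mask, of the two groups' significance
maps encoded as 1-p with sub-threshold voxels zeroed — the closest
reproducible reading of correlating thresholded p-value maps; the full
condition-by-condition cross-correlation matrix is computed and only the
matched-condition diagonal is reported.  Across-condition summaries are
arithmetic mean and (n-1)-denominator sample SD.

Variability: Pearson correlation between whole-brain t-maps for every
unordered pair of subjects within a group (n(n-1)/2 values; 528 + 378 =
906 at full scale) and for every pair of a subject's runs (15 at six
runs).  Groups are compared with a two-tailed pooled-variance t whose
p-value comes from relabeling permutations (20,000 at full scale), with
Cohen's d from the pooled (n-1)-weighted SD and manual Bonferroni
correction at alpha/m over the condition family (m defaults to the number
of conditions compared; 0.05/12 at full scale).  Pair-level values are
treated as independent observations, exactly as in the analysis being
reproduced — pairs sharing a subject are in truth dependent, which is a
known limitation of the pair-level test, documented rather than "fixed".

Structural metrics are normalized as ratios to each subject's total brain
volume; the seven-comparison family (total volume + three normalized
metrics x two hemispheres) is tested the same way at alpha/7.

## Numerical and design choices

- Voxel coordinates are 0-based (x, y, z) indices; NIfTI output uses a
  diagonal affine at the voxel size (default 2 mm).
- Permutation and simulation seeds all derive from one master seed via
  `SeedSequence`; every consumed seed is recorded in the pipeline
  manifest, and fixed-seed reruns are byte-identical.
- Degenerate inputs: empty event tables, rank-deficient designs, zero
  reference counts, zero-variance maps and undersized groups raise errors
  naming the offending field; zero-variance map pairs are excluded from
  correlation sets with a logged warning.
- The minimum attainable FWE p is 1/(n_perm+1) (or 1/N under exhaustive
  enumeration); group sizes below ~5 per group therefore cannot reach
  alpha = 0.05 under one-sample sign-flipping, which is why the shipped
  test profile uses 6+6 subjects.

## Problem sizes used in validation

The test suite and the acceptance script run everything on scaled-down
problems chosen to keep a full validation cycle in the minutes range on
one CPU: grids of 10^3-16^3 voxels, 2-3 conditions, 1-2 runs, 8-16
subjects, 99-2,000 permutations for Monte-Carlo work (the full-scale
profile — 33+28 subjects, 12 conditions, 6 runs, 5,000/20,000
permutations — ships as `PipelineConfig.paper_scale()`).  Calibration uses
200 null-cohort replicates for the group-level FWE rate and 500 for the
pair-level test; planted-effect recovery uses radius 2 vs 4 voxels and
center jitter 0.3 vs 2.4 voxels at 8+8 subjects.  These sizes are large
enough that the type-I checks have 3-sigma Monte-Carlo bands of about
+/-0.05 and the planted effects are recovered with margin.

## Known limitations

- The fixed-effects combination is an unweighted mean, not FSL-style
  inverse-variance weighting.
- The pair-level permutation test ignores the dependence between pairs
  sharing a subject.
- The synthetic noise model is white; no prewhitening is implemented, so
  the GLM would be miscalibrated on real autocorrelated BOLD data.
- Spatial similarity of significance maps depends on the (1-p) encoding
  convention; other encodings (binary masks, t-maps) give different r.
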