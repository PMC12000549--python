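# Methods

## The ALPS model

At the level of the lateral-ventricle body, perivascular spaces run
medio-laterally (the image x-axis), perpendicular to two adjacent white
matter systems: the corticospinal tract ("projection" fibers, oriented
along z) and the superior longitudinal fasciculus ("association" fibers,
oriented along y). Diffusion along x in these two regions therefore has no
fiber-tract contribution and is read as a proxy for glymphatic transport.
The index is

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

where each `D**` term is the arithmetic mean of the corresponding tensor
diagonal map over one ROI, the numerator and denominator average the two
ROI means with **equal weight regardless of voxel counts** (mean of ROI
means, never a voxel-pooled mean), hemispheric indices are computed
separately, and the side-averaged index is the arithmetic mean of the left
and right values. The alternative of pooling both hemispheres' ROIs before
taking the ratio was considered and rejected: left/right indices are
reported side by side, so the average must be consistent with them.

The ratio is axis-convention-sensitive: it assumes x/y/z are anatomically
aligned (right-left / anterior-posterior / inferior-superior) and analysis
happens in native acquisition space with no tensor reorientation. The
tensor-fit module warns when the voxel-to-world rotation exceeds 5 degrees
(configurable), since a rotated grid silently invalidates the ratio.

## Tensor estimation

The diagonal diffusivity maps come from the standard log-linear
least-squares inversion of `S = S0 exp(-b g^T D g)`, solved per voxel for
the six tensor components and `log S0`. Weighted least squares (weights =
squared observed signal, the first-order variance stabilisation for
log-transformed magnitude data) is the default; ordinary least squares is
available and identical in the noiseless limit. Voxels with non-positive
diffusion-weighted signals are fitted on their positive subset and
flagged; fitted negative diagonal values are **retained and flagged, never
clamped**, and ROI means use them as-is with a QC warning — clamping would
bias ROI means in exactly the low-signal voxels where the fit is least
reliable. A design with fewer than six non-collinear nonzero-b directions
raises a rank-deficiency error rather than returning garbage.

## ROI placement

Two routes produce the four masks (projection/association x left/right):

* **Manual**: axis-aligned cubes of edge 6 mm at rater-supplied world
  coordinates, rasterized by voxel-center inclusion over the half-open box
  `[c - 3, c + 3)` mm per axis. On the 2 mm grid this gives the canonical
  3x3x3 = 27 voxels when centered on a voxel center.
* **Automatic**: atlas labels for the SLF (association) and CST
  (projection) are restricted in template space to an axial slab at the
  apex of the lateral ventricles (default 10 mm, z in [-5, 5] mm) and
  trimmed of voxels beyond a lateral distance cap from the midline
  (default 32 mm, the cortex-exclusion margin), then resampled into the
  subject grid through a single template-to-subject transform and
  binarized. Neither the slab nor the margin has a canonical published
  value; both are explicit configuration recorded in output provenance,
  and the defaults are not claimed to replicate any particular rater's
  masks.

Nearest-neighbour resampling is the default interpolation because the
output of a binarization step should itself be binary without a threshold
choice; trilinear interpolation with a configurable threshold (default
0.5) is available. Under an exact integer-voxel translation the
nearest-neighbour transform is a bijection on interior voxels (voxel
counts conserved), which the tests exploit. A transform is a single 4x4
world-space affine or a dense displacement field giving, per target voxel,
the source-space coordinate it pulls from; transform *estimation*
(registration) is out of scope — transforms are applied, not computed.
Any ROI falling below a minimum voxel count (default 2) raises a named
ROI-failure error, and the pipeline excludes that subject with a recorded
reason rather than producing a meaningless index.

## Statistics

* **Age adjustment**: `adjusted_i = raw_i - beta (age_i - age_mean)` with
  `beta` the OLS slope of the raw index on age fitted on **controls only**
  and `age_mean` the control mean age. The model is fitted separately for
  every index variant (method x side), since each has its own age profile.
  Two identities are tested: adjustment is the identity at the control
  mean age, and the adjusted index has exactly zero OLS age slope within
  the fitting sample.
* **ANCOVA**: one-way group comparison with covariates (sex for ALPS;
  age + sex for clinical scores) entered before group. The group F is the
  incremental sum of squares over the covariate-only model against the
  full-model error; with three groups, N subjects and c covariates the
  dfs are (2, N - 3 - c). Partial eta^2 = SS_group / (SS_group +
  SS_error), and the helper identity eta^2 = F df1 / (F df1 + df2) agrees
  with the SS route to 1e-12 on the same data (tested). Post-hoc contrasts
  use Fisher's LSD: covariate-adjusted mean differences over the pooled
  error variance with **unadjusted** two-tailed p — that is the definition
  of LSD, so no extra multiplicity correction is applied. The linear
  algebra is done directly with numpy normal equations; statsmodels and
  pingouin serve as independent cross-checks in the test suite. Under the
  null with an active covariate the empirical type-I error at alpha 0.05
  is calibrated to 5% +/- 1% over 2000 simulated datasets (tested).
* **Effect size for the method comparison**: Cohen's d uses the
  averaged-variance denominator `(mean_a - mean_b) /
  sqrt((SD_a^2 + SD_b^2)/2)`. With summary statistics 1.30/0.18 vs
  1.23/0.16 this yields 0.41, matching the convention used in the
  reliability literature for this comparison; the paired-difference
  variant d_z = mean(diff)/SD(diff) is available behind a flag and is
  roughly 0.69 on the same data — the two are *not* interchangeable.
* **Bland-Altman**: differences a - b (or 100 (a-b)/mean in percent
  mode), limits of agreement bias +/- 1.96 SD, fraction outside the
  limits, and proportional bias as the slope (with p) of the differences
  on the pairwise means. For Gaussian differences about 4.6% of pairs fall
  outside the limits, which the tests verify at large n.
* **Partial correlation**: residualise both variables on the covariates
  (with intercept), correlate the residuals; df = n - 2 - c and p from the
  t transform. With one covariate at n = 132 this gives df 129.
* **Case-control matching**: a seeded greedy 1:1:1 procedure emulating a
  randomized-case-order matching utility: cases are visited in a
  seed-shuffled order and claim the nearest-age unused subject of
  identical sex within an 8-year tolerance from each comparison group;
  incomplete triplets are dropped. Greedy matching is deterministic given
  the seed and never exceeds the exhaustive maximum triplet count, which
  an exponential-search oracle verifies on rosters up to ~12 per group.
* **UPDRS-III subscores**: tremor = items 15-18, bradykinesia = items 2,
  4-9, 14, rigidity = item 3, axial = items 1, 9-13. Item 9 appears in
  both the bradykinesia and axial sets in the source convention; this is
  implemented verbatim and flagged in a code comment as a possible typo
  rather than silently "fixed".
* **Hemisphere lateralisation**: per subject the hemisphere with the
  lower SBR Z-score (more denervated) is labelled most-affected; a paired
  t compares ALPS between labels, with exactly-tied subjects excluded and
  counted.
* Significance is two-tailed alpha = 0.05 throughout. Missing values are
  excluded listwise per analysis.

## The synthetic cohort

The generator defines the study conditions and is first-class, tested
code. Defaults: group sizes 79/57/48 (PD/iRBD/HC); ages normal with
means/SDs 59.5/12.0, 66.5/7.2, 61.5/9.9 years; male fractions
0.61/0.86/0.71; ALPS group means 1.21/1.24/1.28 with age slope
-0.008/year and between-subject SD 0.12; MoCA and MDS-UPDRS I-III group
means/SDs matching the emulated cohort; exclusion probabilities
12/209, 1/209, 12/209 for preprocessing failure, structural abnormality,
and eccentric head position (mutually exclusive, assigned in that order).

The latent per-subject index is `group_mean + beta (age - cohort_mean_age)
+ noise`; clinical scores and DAT-SPECT SBR Z-scores share a Gaussian
copula with the noise component (defaults r = -0.36 for UPDRS-II, -0.25
for UPDRS-III, +0.31 for putaminal and caudate SBR, inside the observed
0.19-0.31 band), and the copula correlation matrix is validated as
positive semi-definite at configuration time. UPDRS-III items are integer
0-4 draws whose Dirichlet-weighted split tracks a latent severity — the
item table is only required to make the subscore sums meaningful, not to
model item psychometrics. A single subject-level latent value drives both
hemispheres plus independent hemispheric noise (SD 0.02, ~2% of the
index), since left/right results are reported as similar.

Imaging: a 24x24x20 grid of 2 mm isotropic voxels (a neighbourhood of the
ventricle body, not a whole head) holds an isotropic background
(0.75e-3 mm^2/s) with two mirrored pairs of anisotropic columns: the
projection columns have Dzz = 1.6e-3 (along-fiber) and Dyy = 0.8e-3; the
association columns the converse. These magnitudes are typical
white-matter values; none is published for the emulated protocol, so all
are configurable. Dxx in both columns is set to `true_ALPS x 0.8e-3`, so
the ground-truth index identity holds *exactly* and noiseless closed-loop
recovery through ROI placement and the index computation is tested at
1e-9. The synthetic atlas labels the four columns (CST left/right 1/2,
SLF left/right 3/4) in template space; per-subject transforms are small
rigid motions (rotation <= 1.5 degrees about z, translation <= 2 mm,
seeded). Subject volumes are painted on region masks obtained by pushing
the template columns through the subject's own transform with
nearest-neighbour resampling — the same operation the automatic ROI route
performs — which is what makes noiseless recovery exact by construction
rather than approximately.

The optional DWI route simulates one b = 0 volume plus 30
Fibonacci-sphere directions at b = 1000 s/mm^2 (S0 = 1000) and fits
tensors per subject. Noise is Rician (Gaussian on two quadrature
channels, magnitude taken) with a Gaussian fallback; the default sigma is
S0/50 (SNR 50, a typical clinical DWI level). Because ROI averaging over
the synthetic columns suppresses signal noise to well under 0.5% of the
index, the per-subject ~2% index variability is deliberately carried by
the hemispheric noise term rather than by implausibly strong signal noise,
which would bias the fitted diffusivities through the Rician floor.

What the simulator does **not** emulate: whole-brain anatomy, partial
volume at tract boundaries, susceptibility/eddy/motion artifacts, rater
variability in manual placement (manual cubes are placed at transformed
column centers, so on noiseless data manual and automatic agree exactly),
and any systematic manual-vs-automatic offset. Passing tests therefore
demonstrate correctness of the computations and calibration of the
statistics, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seed + config reproduces metadata
  tables and volumes bit-for-bit.
* Least squares uses `numpy.linalg.lstsq`; the ANCOVA rejects singular
  designs by rank check rather than silently pseudo-inverting.
* An ALPS denominator <= 0 raises an undefined-index error; a failed
  hemisphere still reports the valid side with the average flagged
  undefined.
* Matching ties on age are broken deterministically by subject id.
* Chi-square for sex tables is the plain Pearson statistic without
  continuity correction.
* Problem sizes in the test suite are chosen at desk scale: the
  end-to-end recovery runs one 184-subject cohort on the 24x24x20 grid
  (~3 s), and the type-I calibration uses 2000 replicates of n = 60
  (~1 s) — both comfortably reproducible on a laptop.

## Known limitations

* The automatic-ROI restriction parameters (slab, lateral cap) are
  defaults, not a validated reproduction of any published mask set.
* The greedy matcher emulates, but does not claim bit-compatibility with,
  proprietary matching utilities.
* The simulator's homogeneous columns make the manual and automatic
  routes agree almost perfectly; real manual/automatic offsets arise from
  heterogeneity the phantom does not model.
* Registration (transform estimation) and DWI preprocessing are out of
  scope; the pipeline assumes clean, co-registered inputs.
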