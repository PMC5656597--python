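# Methods

This note records the models implemented in `lateralink`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Data model and geometry

All volumes live on a shared `VolumeGrid` (dims, 4×4 affine; MNI sign
convention, +x right). Voxel data are flat C-ordered vectors; a BOLD run is
`(T, V)`. Mask algebra requires exact grid equality (affines within 1e-4);
there is no resampling — cohorts are generated already aligned, and
registration is out of scope.

Hemisphere masks split a brain mask at the world plane x = 0; voxels whose
centre lies exactly on the plane belong to *neither* hemisphere, so
laterality counts can never double-count midline tissue. On the default
phantom grids the x dimension is even and no centre hits the plane.

Spherical ROIs include every voxel whose centre is within the radius; a
6 mm sphere on a 3 mm grid centred on a voxel centre therefore has exactly
33 voxels (lattice points with i²+j²+k² ≤ 4).

## Motion and quality control

Framewise displacement is the sum of absolute backward differences of the
six rigid-body parameters, with rotations converted to arc length on a
50 mm sphere — the radius conventional for this formulation. Exclusion
criteria: any |translation| > 1 mm, any |rotation| > 1°, or max FD ≥ 0.5 mm.
Rotations are stored in radians in motion TSVs; a `degrees` dialect flag is
provided, and the QC limit is applied in degrees.

## Resting-state preprocessing

Fixed order: (1) nuisance regression (six motion parameters plus
white-matter and ventricular mean signals, intercept added), (2) temporal
band-pass 0.01–0.08 Hz, (3) linear detrend. The ordering of filtering and
detrending is a convention; with a zero-phase filter and a linear trend the
two nearly commute, and the residual DC/trend after filtering is minute.

The band-pass is a zero-phase forward–backward Butterworth of order 2 with
even-extension padding. The filter family is an implementation detail; the
contract is behavioural: ≥ 90 % amplitude retained at 0.04 Hz, ≤ 10 % at
0.005 Hz and at DC, for TR = 3 s.

Spatial smoothing is an isotropic Gaussian specified by FWHM
(σ = FWHM/√(8 ln 2)), applied with reflective boundaries so constants are
preserved exactly and total mass is conserved. Smoothing is applied to
connectivity z-maps *before group comparison*, not to raw runs.

## Task model

The block design alternates semantic and control 30-s blocks (default four
pairs, TR 3 s → 80 volumes). Regressors are boxcars convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6), built on a
0.1 s lattice and sampled at the TR. The kernel is normalised to unit sum,
so a sustained block converges to the block amplitude in data units —
making the percent-signal-change estimate
`100 · (β_semantic − β_control) / β_intercept` directly interpretable.

Per-voxel statistics are OLS with intercept and centred linear drift;
`t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`, df = T − p. No prewhitening is applied;
with AR(1) noise the null t values are overdispersed (a known property of
unwhitened OLS), which matters only for calibrated false-positive-rate
claims, not for the contrasts and ratios this package reports.

Group comparison of subject maps: voxel-wise OLS on
`[1, group, centred covariates]` with the group-coefficient t and
Benjamini–Hochberg FDR across in-mask voxels (default q = 0.01). Task
covariates are age, sex (F=0/M=1), education, mean FD and the handedness
inventory score; the last is nearly collinear with group and triggers a
condition-number warning while proceeding — by design, since the original
analysis specified it. Conjunction maps use the minimum statistic
(`min(t₁,t₂) > threshold`), the valid-by-default conjunction-null test.
Seeds are the regional t maxima, ties broken to the smallest flat voxel
index.

## Threshold-free laterality index

For a subject t-map and a compartment (cerebral or cerebellar), both
hemisphere masks are swept with one shared threshold grid; each side's
count curve N(θ) is fitted by the default log-linear family
`ln(N+1) = a − bθ` and summarised by `A = e^a − 1`; then
`LI = (A_L − A_R)/(A_L + A_R)`. Alternative families (`linear`,
`gaussian` in θ²) are available and chosen by best R² when configured; the
family used is recorded in the fit diagnostics. If both constants vanish
the LI is undefined and flagged rather than forced to 0.

**Threshold grid.** Default: 20 evenly spaced points from the one-sided
p = 0.001 critical value of the map's distribution up to the in-mask
maximum. The lower bound matters: below significance, suprathreshold counts
are dominated by noise voxels, which are hemispherically symmetric in
expectation. Because the regression constant extrapolates the *level* of
the count curve, symmetric noise inflates A_L and A_R equally and drives LI
toward 0 regardless of true asymmetry; starting the sweep in the
significant range keeps the counts activation-dominated, and any remaining
shared extrapolation bias cancels in the LI ratio. Verified by simulation:
with the significant-range grid, planted laterality in
{−0.4, 0, 0.2, 0.5, 0.8} is recovered with |bias| ≤ 0.05 (per-subject SD
0.08–0.3, shrinking with activation strength).

Categorical calls: left-lateralized (LI ≥ 0.2), right-lateralized
(LI ≤ −0.2), non-lateralized otherwise — boundaries inclusive exactly as
stated.

## Seed-based connectivity

The seed signal is the mean series over the ROI. Voxel-wise Pearson r is
Fisher-transformed with r clipped to ±(1 − 1e-7), so seed voxels (r = 1)
map to a finite z ≈ 8.4; zero-variance voxels get z = 0 and are reported in
a flag list instead of propagating NaNs.

## Cluster-extent inference

The group model on z-maps uses age, sex and mean FD as covariates. Residual
smoothness per axis comes from the Gaussian-autocorrelation estimator: with
neighbour correlation ρ̂ = 1 − s²/(2σ̂²) (s² the mean squared spatial first
difference), σ_g² = −Δx²/(4 ln ρ̂) and FWHM = √(8 ln 2)·σ_g. White noise
gives ρ̂ ≤ 0 → FWHM 0; smoothing white noise with a Gaussian kernel is
recovered exactly in expectation (ACF of the smoothed field is Gaussian
with twice the kernel variance).

The Monte-Carlo null simulates unit white noise on the grid's bounding box,
smooths to the estimated FWHM with zero padding, and standardises by the
*exact per-voxel* sd of the smoothed field (separable closed form), so edge
voxels are correctly calibrated rather than under-weighted. Voxels exceed
at the two-sided voxel p (default 0.01); positive and negative excursions
are labelled separately with 26-connectivity (6/18 configurable); the
extent threshold k is the smallest size whose familywise exceedance
probability is ≤ α (default 0.01, 10 000 iterations by default). The
observed map is thresholded and labelled identically; cluster records carry
the peak world coordinate, signed peak t, extent and member voxels, with an
optional integer label volume for region naming. The seed's own
neighbourhood is excluded from the difference search in the pipeline, since
its self-correlation is structural.

Familywise-error control was validated on 200 full-null replicate cohorts
(28+28) through the entire resting pipeline: the fraction of datasets with
any surviving cluster stays within twice the Monte-Carlo standard error of
the nominal α = 0.01.

## Association

Per cluster, per group (and pooled for recovery studies), mean z is
correlated with cerebral LI by Pearson's r (two-sided t, df = n−2) and
Shepherd's pi. Outliers for the latter: for each of 200 bootstrap
resamples, the squared Mahalanobis distance of every original point to the
resample's mean and covariance is computed; points at an average distance
≥ 6 (i.e. mean squared distance ≥ 36) are removed. Under a clean bivariate
normal cloud the squared distance is ~χ²(2), so distance 6 is effectively
unreachable without genuine contamination — the removal only fires on
influential points, and the Spearman p on the retained points is doubled
(capped at 1) to pay for it. No correction across region pairs is applied.

## Synthetic cohorts

The generator emulates the study design on a desk-scale phantom: a
superellipsoidal "brain" (20×24×20 at 3 mm by default) split at x = 0, an
inferior cerebellar slab (z below 0.4 of the inferior semi-axis), central
white-matter and ventricle stand-in masks, and four mirrored 6 mm regions
(frontal pair, cerebellar pair).

* **Groups and covariates.** 28 subjects per group; ages ~N(24.2, 2.5) /
  N(24.7, 1.9); handedness scores truncated-normal within [−100, −50] and
  [50, 100]; education ~N(16, 2).
* **Noise.** AR(1) in time (φ = 0.3, unit marginal variance, SD 1 % of the
  100-unit baseline), spatially independent. Motion is a per-parameter
  random walk (0.01 mm / 3·10⁻⁴ rad steps), giving mean FD ≈ 0.06 mm and
  max < 0.2 mm so the whole cohort passes QC, as in the emulated study.
* **Connectivity.** A unit-variance latent series per seed region; seed
  voxels carry it with weight 0.9, target voxels mix it with weight
  `w = r/√(1−r²)` so the voxel-to-latent correlation is exactly the planted
  r. Defaults: seed–cerebellar r = 0.55 (LH) vs 0.30 (RH), a Fisher-z
  difference of ≈ 0.31.
* **Laterality.** Each mirrored pair responds at a common per-voxel
  amplitude (default 2 % of baseline, chosen so single-subject peak t is
  ~8–12 as in robust block designs); the planted LI splits the *recruited
  extent*: the left region activates its ⌈n(1+LI)/2⌉ voxels nearest the
  region centre, the right ⌈n(1−LI)/2⌉, so the ground-truth
  LI = (m_L−m_R)/(m_L+m_R) is the voxel-count quantity the threshold-free
  index estimates. Laterality expressed as amplitude asymmetry at equal
  extent is *not* recoverable by any count-constant index (both count
  curves have the same zero-threshold level), which is why dominance is
  planted as recruited extent at matched strength.
* **Individual differences.** Group LI defaults: cerebral 0.0 (LH) / 0.5
  (RH); cerebellar 0.0 / −0.4. Per-subject deviations of (cerebral LI,
  seed–target Fisher z) are bivariate normal with SDs 0.10 and 0.20 and
  correlation −0.6 — the planted laterality–connectivity association.
  Amplitudes get a shared lognormal jitter (SD 0.1).

Everything is reproducible from a single integer seed via spawned
per-subject, per-component streams; omitting a component (e.g. task runs)
leaves the others bit-identical.

**What the phantom does not emulate:** physiological noise and its spatial
correlation structure, spatial autocorrelation of the raw noise,
registration/normalisation error, susceptibility dropout, real anatomy
(region sizes and distances are phantom-scale), event-related designs, and
behavioural responses. Passing recovery tests therefore demonstrates the
*estimators* are correct and calibrated under the stated noise model, not
that effect sizes from real cohorts will match.

## Problem sizes used in validation

Recovery and error-control studies run at reduced scale: phantom grids
12×14×12 to 14×16×14 at 3 mm, 60–80 resting volumes, z-map smoothing 3 mm
(the 8 mm kernel scaled to the phantom brain's ~1/3 linear size), 1000–2000
Monte-Carlo iterations inside replicate loops and 10 000 for single null
distributions. The full-scale defaults (20×24×20 grid, 120 resting volumes,
8 mm smoothing) are used when no replication loop is involved.

## Known limitations

* OLS without prewhitening overdisperses null t statistics under AR(1)
  noise; voxel-level p-values from task GLMs are approximate (cluster-level
  inference calibrates against the realised residual field, so the
  familywise claim is unaffected).
* The threshold-free LI's per-subject sampling SD at phantom scale
  (0.1–0.3) is larger than in whole-brain data, where counts are thousands
  of voxels; group means are accurate to ~0.02.
* A region may be the target of only one seed's latent in the generator;
  overlapping connectivity graphs need explicit construction.
* The smoothness estimator assumes a stationary Gaussian ACF; strongly
  non-stationary residuals would need a local estimator.
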