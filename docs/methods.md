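# Methods

This note documents the models implemented in `ctvbm`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical decisions a maintainer should know about.

## Coordinate conventions

Voxel indices are 0-based; the world frame is RAS in millimetres; a
volume's affine maps voxel index to world position.  All module boundaries
exchange world coordinates.  Resampling is always a world-space pull-back
(trilinear for intensities and probabilities, nearest-neighbour for
labels), with out-of-field voxels set to 0; CT volumes are intensity-
windowed before any resampling so that 0 is their background value.

## CT brain extraction

Brain parenchyma and CSF occupy a narrow Hounsfield band, so extraction is
a windowing-plus-morphology recipe: soft-tissue candidates are voxels with
`lo < HU <= hi` (default window (0, 100] HU, bone excluded above 300 HU);
the largest 6-connected component is kept — the skull lies outside the
window and severs the brain from scalp, and the head-holder slab is a
smaller separate component — then closed with a 4 mm structuring element
and hole-filled.  The background of the returned volume is set to `lo`;
because candidacy is strict at the lower bound, re-running the extraction
on its own output reproduces the same mask (idempotence).  The lower bound
is strict *by design*: an inclusive bound would make the filled background
a candidate and the operation non-idempotent.

## Tissue segmentation

The segmenter is a spatially-weighted Gaussian mixture: class `c` owns
`n_c` Gaussians, and the posterior responsibility of Gaussian `g` of class
`c` at voxel `v` is proportional to `prior_c(v) · w_g · N(y_v; μ_g, σ_g²)`.
EM runs on a voxel subsample (the `sampling_distance_mm` grid step) and
the class posteriors are evaluated at full resolution on exit.

Presets follow the two acquisition regimes:

- `mr-default`: `n_gauss = (2, 2, 2, 4)` for (GM, WM, CSF, other), a
  multiplicative bias field with light quadratic regularization (1e-2),
  3 mm sampling.
- `ct-default`: `n_gauss = (2, 2, 3, 4)` with the CSF+other total tunable
  over 6–8 per subject, bias model disabled (Hounsfield units are
  calibrated, so "heavy regularization" of intensity nonuniformity is
  taken to its limit: none is modelled), 2 mm sampling.

`auto_adjust_gaussians` emulates per-subject tuning "until successful
segmentation": every candidate in the grid (GM, WM ∈ {1, 2}; CSF+other
totalling 6–8) is fitted with the same seed; a fit is successful when EM
converged and the GM posterior (> 0.5) reaches Dice ≥ 0.6 against the
prior-MAP GM labelling — the guard against gray matter leaking into bone
or CSF — and among successful fits the highest mean per-voxel
log-likelihood wins, with exact ties going to the smaller model.

Numerical choices:

- **Prior floor 0.05.** Tissue priors are population averages and no
  location is certain of its class (at map resolution real cortex is
  interleaved with sulcal CSF), so each class keeps at least 5% prior mass
  everywhere.  Without the floor a confident prior can hard-veto clear
  intensity evidence — it would, for instance, relabel focally lost tissue
  back to gray matter.
- **Initialisation** seeds per-class Gaussians at dominant histogram peaks
  of the prior-MAP class voxels (quantile fallback); plain quantiles would
  bury minority modes such as scalp inside the air-dominated "other"
  class.
- **Variance floors.** The M-step maximizes under the constraint
  `σ² ≥ 1e-5 · var(y)` (a constrained M-step is still a monotone GEM
  step); a closed-form variance below `1e-8 · var(y)` is treated as a
  collapse and triggers a jittered restart (up to 3).
- **Background exclusion.** A single exact intensity value covering more
  than a quarter of the volume (the constant background left by brain
  extraction) is excluded from the fit: a zero-variance spike has no
  Gaussian representation.  Posteriors are still evaluated everywhere,
  with prior fallback where all Gaussians underflow.
- **Bias field** (MR only): a separable 4³ cosine basis for the log-bias,
  refreshed every second EM iteration by weighted ridge regression of
  `log(y / μ̂)` with delta-method weights `μ̂²` (so near-zero air voxels,
  whose log-ratios are pure noise, carry no influence); an update is
  accepted only if the penalized likelihood improves, which preserves the
  monotone-likelihood guarantee.
- EM stops at a relative log-likelihood change of 1e-4 or 64 iterations.

## Spatial normalization

A 12-parameter affine (translation, rotation, log-scale, shear) minimizes
the mean squared intensity difference to the GM template after closed-form
optimal global intensity scaling, by a deterministic Powell search from a
centre-of-mass plus second-moment initialisation.  The nonlinear
refinement optimizes a separable low-frequency cosine (DCT) displacement
basis under a membrane-energy penalty by Gauss-Newton with step halving,
so the objective trace is monotone non-increasing by construction.

The warp "cutoff" is the shortest represented spatial wavelength in mm;
bases per axis = `max(2, floor(FOV / cutoff))`.  The CT arm uses 35 mm and
the MR arm 25 mm (the MR basis is the more flexible one).  The penalty is
`reg_lambda` times the grid-mean squared displacement gradient; the
default `reg_lambda = 0.1` leaves millimetre-scale anatomical warps
essentially free while suppressing noise-driven deformation, and — not
incidentally — limits the warp's ability to "close" a genuine focal
lesion.  Normalization parameters are estimated on an 8 mm-smoothed copy
of the GM map (matching the template's own smoothness and denoising the
objective) and applied to the unsmoothed map.

A note on identifiability: displacement components along image level sets
(and over empty regions) are unobservable, so individual basis
coefficients are gauge-dependent; validation therefore checks the
recovered displacement *field* over the template support, not single
coefficients.

No Jacobian modulation is applied by default: the smoothed, unmodulated
GM density is analyzed, under the reading that after wide smoothing
regional intensity is an adequate proxy for regional GM volume.

## Smoothing

Separable Gaussian, `σ = FWHM / (2√(2 ln 2))` per axis in voxel units,
kernel truncated at 4σ, zero padding (GM maps are zero outside the head,
so zero is the physically consistent boundary).  Default FWHM 12 mm.

## Statistics

Globals use the classic two-pass rule (mean of voxels above overall
mean / 8); proportional scaling rescales each image so its global equals
the cohort mean.  The voxelwise model is a two-group cell-means GLM with a
pooled-variance t contrast (controls minus patients, one-tailed for GM
decrease), df = n − 2; `t_to_z` maps through the exact tail functions so
|t| up to ~40 converts without saturation.  The analysis mask keeps voxels
whose across-subject mean density exceeds 0.05, suppressing spurious edge
clusters.

Cluster inference:

- **Random-field mode (default).**  Residual smoothness is estimated from
  standardized residual spatial derivatives under a Gaussian
  autocorrelation model.  The expected cluster count uses the 3-D
  Euler-characteristic density of a *t*-field with the map's degrees of
  freedom at the t threshold (the Gaussian density is a poor approximation
  at df = 10); expected suprathreshold volume is `S · voxel_p` exactly.  A
  single cluster's extent then follows
  `P(n ≥ k) = exp(−β k^{2/3})`, `β = (Γ(5/2) · E[m] / E[N])^{2/3}`.
  Uncorrected cluster p-values enter Benjamini–Hochberg selection across
  clusters at q = 0.05 (topological FDR); a family-wise variant
  (`corrected=True`) is available for comparison against permutation.
- **Permutation mode.**  Group labels are permuted; the maximum
  suprathreshold cluster size per permutation forms the null, and each
  observed cluster gets `p = (1 + #{max ≥ k}) / (n_perm + 1)`.  These
  p-values are family-wise corrected by construction (maximum statistic),
  so the pipeline compares them to q directly rather than re-applying BH.

Extent thresholds default to 123 voxels (CT arm) and 381 voxels (MR arm)
on the 2 mm analysis grid — 984 and 3048 mm³ — and are configuration, not
semantics; scaled-down experiments use the same physical volumes at their
own voxel size.  Connectivity defaults to 18.

## The head phantom

The phantom is a nested-ellipsoid head: WM core, a 10 mm cortical GM
shell whose inner boundary is perturbed by seeded sinusoids (a crude
gyrification stand-in), a 2.5 mm subarachnoid CSF rim, ellipsoidal
ventricles, skull and scalp shells, and an optional detached head-holder
slab.  CT tissue means (air −1000, CSF 8, WM 27, GM 35, skin 40, holder
60, skull 1000 HU) put the GM/WM contrast at a realistic 8 HU; MR means
follow T1 ordering (CSF 10 < GM 60 < WM 90) with an optional smooth
multiplicative bias field.

Anatomy is maintained as *tissue fractions*: labels are drawn on a
2×-supersampled grid and block-averaged, so scanner voxels at boundaries
carry partial-volume mixtures rather than whole-voxel jumps.  Per-subject
variability composes a small random affine (log-scale sd 0.02, rotation
sd 2°, translation sd 2 mm) with a smooth random warp of 2 mm peak
amplitude — enough inter-subject variability to make normalization
non-trivial without breaking it — applied to the fraction channels by
trilinear pull-back (linear interpolation of fractions is exactly the
partial-volume model for a resampled mixture).

Focal atrophy inside the pipeline-level cohorts is modelled as coherent
tissue destruction: all GM within a concentric sub-sphere holding the
`severity` share of the target sphere's GM mass converts to CSF, the same
sub-region in every patient (the disease targets an anatomical structure),
individualized only by each subject's jitter.  The expected in-sphere GM
loss equals `severity`, matching the voxelwise Bernoulli model that the
label-level `apply_atrophy` operation implements.  Voxelwise salt-and-
pepper conversion was rejected for the cohort model because spatial white
noise at the render-voxel scale is destroyed by any sub-voxel resampling —
real tissue loss is contiguous.

A fast "density cohort" path builds template-space smoothed GM maps
directly (GM fraction plus smoothed voxel noise), skipping rendering,
segmentation and normalization.  It is used for calibrating the inference
machinery at scale: under label exchange the per-subject processing chain
is a fixed preprocessing and cannot alter the type-I error of the
permutation test, so null calibration measured on density cohorts applies
to the machinery the full pipeline uses.

What the phantom does *not* emulate: realistic cortical folding, beam
hardening and streaking (CT), k-space artifacts and anatomical T1
heterogeneity (MR), and anatomical population variability beyond smooth
geometric jitter.  Passing phantom tests therefore demonstrates the
correctness and calibration of the algorithms, not clinical performance.

## Validation experiments and problem sizes

All cohort-level experiments run on a 48³ grid at 4 mm voxels (192 mm
field of view) with 7 controls vs 5 patients; segmentation samples every
8 mm; the lesion is a 30%-severity, 10 mm-radius sphere in the inferior
medial cortex.  Detection runs 25 seeded replicates for the CT arm and 15
for the MR arm; null calibration runs 200 seeded density cohorts with 199
permutations each.  Segmentation accuracy (Dice) is scored on an 80³ /
2.4 mm grid, where partial-volume ambiguity does not dominate the score.
These sizes keep a full validation run within tens of minutes on one CPU.

## Known limitations

- At 4 mm test resolution the MR arm is structurally disadvantaged: a
  lesion voxel that loses its GM to CSF but retains WM partial volume
  renders at `0.5·90 + 0.5·10 ≈ 50`, inside the normal GM intensity band —
  in T1, WM+CSF partial voluming mimics GM.  Half of a 10 mm lesion's
  voxels are such boundary voxels at this scale, so the visible MR effect
  is roughly halved and varies strongly between patients, and the MR arm's
  lesion-detection rate falls far below the CT arm's.  At clinical MR
  resolution (~1.25 mm) boundary voxels are a thin minority and this
  degeneracy largely vanishes; it should be read as a property of the
  scaled-down phantom study, not of MR morphometry.
- The random-field cluster model assumes stationary smoothness; residual
  smoothness from misregistration is spatially variable, and the global
  estimate makes edge clusters somewhat miscalibrated (the permutation
  mode exists as the exact-calibration alternative).
- The affine optimizer is a bounded Powell search; with heavily displaced
  or rotated heads (beyond the centre-of-mass + moments initialisation's
  capture range) it can converge to a local optimum.
- `auto_adjust_gaussians` ranks by penalized-free likelihood, so among
  successful fits larger mixtures usually win; the tie-break toward fewer
  Gaussians only applies to exact ties.
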