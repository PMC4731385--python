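# Methods

## Image model and pipeline assumptions

The pipeline treats a brain-extracted 3-D FLAIR volume as a mixture of three
intensity populations — nonbrain/CSF (darkest: fluid is suppressed by the
inversion recovery), white matter, and gray matter (brightest normal tissue)
— plus hyperintense outliers (lesions, septum pellucidum, some midbrain gray
structures). Every stage depends on that ordering, CSF < WM < GM < lesion,
and on lesions being far brighter than the GM mode. Images that violate it
(e.g. heavy bias fields collapsing the contrast) are outside the model;
bias-field correction is deliberately not included.

All distances and kernel widths are specified in millimetres and converted
to voxels per axis with the image voxel dimensions, so defaults keep their
meaning on anisotropic grids. Voxel indices are 0-based; world coordinates
come from the NIfTI affine; plane distances are unsigned perpendicular
distances of voxel *centres*.

## Stages and the choices behind them

**Brain mask.** A user-supplied mask is preferred. The fallback estimator
thresholds at 0.3 × the median nonzero intensity, closes once with a 3³
element, fills holes and keeps the largest 26-connected component. It is a
plain robust-threshold stand-in for a surface-based brain extractor and is
adequate when the background is already near zero. NaNs inside the brain
mask abort the run; NaNs outside may be blanked at load time.

**Smoothing.** σ = 0.5 mm separable Gaussian, mirror (reflect) boundary
padding so interior intensity sums are conserved. Masking happens first,
then smoothing, matching the originating toolchain order; background zeros
therefore participate in the convolution at the brain edge.

**Tissue fit.** A 3-class univariate Gaussian mixture is fit by EM on *all*
in-mask voxel intensities (no histogram binning — exact and simpler, and
equivalent in the large-sample limit). Initialization is deterministic:
means at the 10th/50th/85th intensity percentiles (matching the expected
CSF-minority / WM-bulk / GM composition), equal weights, common sd = sample
sd. Convergence: relative log-likelihood change < 1e-8 (1e-6 proved too
loose — with n ≈ 10⁵ the absolute threshold is large enough to stop EM in
the middle of the slow plateau where the overlapping WM/GM components are
still separating, leaving means off by several percent). Component sds are
clamped at 1e-3 of the data range rather than treated as fatal: a noise-free
image legitimately concentrates a class on a point mass. A component that
loses all responsibility mass triggers a jittered restart (≤ 5, seeded).
Argmax ties break to the lower class index. No MRF spatial prior and no
partial-volume model (see Limitations).

**Hyperintensity capture.** Voxels brighter than `μ_GM + z·σ_GM` (z = 3.5)
join the nonbrain class — the explicit, deterministic substitute for the
behaviour of histogram-fitting segmenters that mislabel lesions as nonbrain.
A one-shot application of the rule is self-defeating: the lesions themselves
inflate σ_GM (14.8 vs ≈ 5 clean on the default phantom) and push the
threshold above their own intensities. The estimates are therefore made
robust by alternating (a) an EM fit on currently non-captured voxels with
(b) recomputation of the threshold, until the captured set is stable
(typically 3–4 rounds). The fixed point leaves the tissue fit describing
tissue only and settles the threshold in the intensity gap between the GM
mode and the hyperintensities. Raising z can only shrink the captured set.

**Gap threshold.** The nonbrain-class intensities are binned into equal-width
bins spanning [min, max]; bins are scanned from the dark end and the first
*empty* bin stops the scan; the threshold is that bin's **upper edge** and
candidates are strictly above it, so the empty bin and everything darker is
removed. If no bin is empty the image is flagged `no_gap_found` and yields
zero lesions — a lesion-free subject is a valid result, not an error.

*Bin count.* The default is 32 bins. The bin width must exceed the spacing
of the smallest order statistics of the dark (CSF) noise tail, which for a
Gaussian tail is ≈ σ/z_N (σ the effective post-smoothing noise sd, z_N ≈ 4
at these sample sizes); with fine bins an empty bin appears immediately
above the darkest sample and the scan stops before removing any CSF. On the
default phantom at noise sd 4, 256 bins failed 15/15 seeds, 128 failed
13/15, 64 failed 2/15 and 32 failed 0/15; 32 bins keeps the width ≈ 2× the
effective noise sd while remaining far narrower than the CSF–lesion gap.
The count is configurable (`histogram_bins`, minimum 16).

**Connected components.** 26-connectivity by default (6 and 18 available).

**WM-overlap filter.** The WM mask is `P(WM) > 0.7` (strict, literal
reading of "above"). Components with ≥ 1 voxel inside it are kept whole;
everything else is removed whole; ids are re-densified. The WM probability
map is either supplied in subject space or propagated from an atlas by a
moments-based affine (centre of mass + principal axes + per-axis scale from
second moments) — deliberately simpler than nonlinear registration, which
is out of scope. Trilinear resampling, out-of-field = 0.

**Midline filter.** A component whose minimum distance to the mid-sagittal
plane is ≤ 4 mm (inclusive — "touch or come close") has its voxels at
distance ≤ 9 mm (inclusive) deleted; voxels beyond 9 mm are *never* deleted,
and surviving fragments are re-labelled as fresh components. This truncated
removal preserves the distal part of periventricular lesions contiguous with
the bright septum. The plane comes from the atlas through the registration
affine, or, without an atlas, through the brain-mask centroid with normal
along the x axis. Both filters only delete voxels and are idempotent.

**Volumetrics.** Brain volume = WM + GM hard labels ∪ final lesion voxels
(lesions are brain tissue; CSF excluded — the usual brain-tissue convention
of atrophy pipelines such as SIENAX). Lesion filling sets final lesion
voxels to WM with posterior (0, 1, 0) before tissue volumes are read off.
ICV normalization multiplies by `ICV_standard / ICV_subject`: this is the
direction that yields a volume measure in standard space (a small head is
scaled up), matching the SIENAX convention; descriptions of this scaling are
sometimes worded with the ratio inverted, so the implemented direction is
stated here explicitly. The subject ICV is approximated by the brain-mask
volume (tissue + CSF); callers may supply a measured ICV.

## The synthetic atlas

The packaged "standard space" is the noise-free standard phantom rendered at
runtime (1 mm isotropic): brain mask, WM probability (binary WM blurred with
a 1 mm Gaussian, clipped to [0, 1]), exact mid-sagittal plane, standard ICV,
and a FLAIR-like reference volume. It is synthetic by construction and
exists so registration and mask propagation are fully testable offline;
users with real standard-space files can substitute them anywhere an
`AtlasBundle` is accepted. The subtraction recipe for building a FLAIR-like
reference from a T2 standard and a CSF mask (`clip(T2 − CSF, 0)`) is
provided as `make_flair_like_reference`.

## The phantom: what it emulates, what it does not

Geometry: a triaxial brain ellipsoid (semi-axes 38/46/34 mm — triaxial so
the principal axes of the moments registration are unambiguous) containing,
outside-in, a 2 mm sulcal CSF rim (brain extraction leaves sulcal CSF, and
the dark side of the nonbrain histogram must be densely populated for the
gap search, as it is in real images), a 3 mm cortical GM shell, a WM core,
two mirrored ventricles, a bright 1.5 mm-half-thickness septum sheet between
them, and spherical lesions. Palette: CSF 20, WM 55, GM 70, septum 120,
lesion 130; additive Gaussian noise (default sd 4 ≈ 6% of GM — a realistic
within-tissue spread) inside the brain only; intensities clipped at 0;
background exactly 0. The mid-sagittal plane is exactly x = nx/2 in world
mm. Default lesion load: three deep-WM spheres of radius 7/5/4 mm ≈ 1.06% of
brain volume, all > 9 mm from the midline.

The validation suite (`default_validation_suite`) fixes five scenarios:
lesion-free, single deep-WM lesion, periventricular lesion contiguous with a
tall septum and spanning past 9 mm, septum-only, and an enlarged-ventricle
variant whose septum sits ≈ 7 mm lateral — beyond the 4 mm touch gate — so
the midline false positive *survives*, reproducing the method's documented
atrophy failure mode.

Not emulated: MRI physics (bias fields, Rician noise, partial volume beyond
voxelized geometry), gyral folding, real lesion texture or location priors,
and spatially correlated tissue heterogeneity. Passing phantom tests
demonstrates the algorithmic contract (thresholds, filters, bookkeeping,
recovery under additive noise), not clinical segmentation accuracy.

## Statistics module

- Outliers: |x − mean| ≥ k·sd (k = 3), sd with n−1 denominator, single pass
  on the full sample, inclusive boundary; removal is once, not iterative.
- Transform selection: among domain-admissible candidates (identity, sqrt,
  log10, inverse) the highest Shapiro–Wilk W wins; identity is kept when
  within 0.005 of the best (an explicit, deterministic replacement for
  by-eye normality checks). The inverse transform's order reversal is
  flagged with a warning.
- Pearson p-values: two-tailed via t = r·√((n−2)/(1−r²)).
- Partial correlation: Pearson on least-squares residuals (intercept
  included), df = n − 2 − k; reduces exactly to Pearson at k = 0.
- HMR: OLS per stage; ΔR² F test with (q_m, n − p_m − 1) df; standardized
  betas from the z-scored final model with per-coefficient t tests.
- Missing data: listwise deletion per analysis. p-values are reported to 3
  decimals in tables, full precision retained internally.
- The synthetic cohort generator draws from a multivariate normal whose
  target correlation matrix mimics a moderately disabled MS cohort
  (log-lesion burden vs walking/processing-speed measures ≈ −0.44…−0.51,
  age as a nuisance correlate), then maps columns onto measurement scales
  (log10-normal T2LV around 0.86%, volumes ~7×10⁵ normalized mm³, etc.).
  Clipping/rounding to instrument ranges slightly attenuates extreme
  correlations; the planted values are recovered within sampling error.

## Problem sizes and runtime

Default phantom 96³ voxels at 1 mm (≈ 2.4×10⁵ brain voxels); a full
pipeline run takes ≈ 10–15 s on one CPU, dominated by the EM iterations.
Validation sweeps use 20 runs (10 seeds × 2 lesion loads); mixture-recovery
checks use 10⁵ samples; the gap-threshold oracle uses 1000 random
histograms. These sizes make the whole suite and the acceptance script run
in minutes while keeping every estimate comfortably in its asymptotic
regime.

## Known limitations

- No partial-volume model: hard labels misassign boundary voxels; on the
  phantom the thin GM shell reads ≈ 10% low while WM+GM together is within
  2%. Lesion volumes are unaffected at the ±15% level because the capture
  threshold settles near the WM/lesion partial-volume midpoint.
- Moments-based affine registration cannot follow nonlinear anatomy; the
  midline filter inherits that approximation (and the atrophy failure mode
  is reproduced by design, not fixed).
- The 3-class EM degrades when noise approaches the WM/GM contrast (at
  phantom noise sd 8 ≈ 11% of GM the third component can latch onto the
  hyperintensity cluster instead of GM); scenario tests document this as
  expected degradation rather than masking it.
- The gap search assumes a dense dark-intensity population; on images whose
  nonbrain class lacks one (tiny CSF samples, aggressive masking) the scan
  can stop in the noise tail. The 32-bin default guards this for realistic
  noise; `histogram_bins` trades gap resolution against tail robustness.
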