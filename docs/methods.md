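# Methods

## The segmentation model

White matter hyperintensities are, by definition, outliers on the bright
side of the FLAIR intensity histogram. `wmhseg` models them with a
single global statistic: after pre-processing, a voxel is classified as
lesion when its intensity is at least μ + k·σ, where μ and σ are the
mean and standard deviation of all brain-voxel intensities and k
defaults to 1.5. The model makes three assumptions:

1. lesion voxels are globally, not just locally, hyperintense — true on
   FLAIR, where CSF is suppressed and normal tissue spans a narrow band;
2. lesion load is a small fraction of the brain, so lesions inflate μ
   and σ only mildly (at very high loads the threshold rises with the
   load, making the estimate slightly conservative);
3. non-lesion hyperintense structures have been removed beforehand —
   which is exactly what the skull-stripping and the cerebellum/brainstem
   exclusion are for; anything that survives (septum pellucidum,
   flow artifacts) is handled by the manual-edit step.

No spatial model, tissue prior or training data is used; this is the
method's point — it is transparent, fast and fully reproducible.

## Pre-processing

Order of operations: FLAIR→T1 co-registration, brain-mask
multiplication, T1→template registration (FLAIR carried along the
composed transform), exclusion-mask removal, Gaussian smoothing. The
intensity statistics are computed after smoothing, on the final
template-space image.

* **Brain mask** — the sum of GM, WM and CSF maps binarized at 0.5
  (configurable). With probabilistic maps this is a majority rule; with
  binary maps that partition the brain any threshold in (0, 1] is
  equivalent. Tissue segmentation itself is an input, not part of this
  package.
* **Registration** — intensity-based affine (6 or 12 degrees of
  freedom; default 12). Cost is one minus the correlation ratio of the
  moving intensities binned against 32 fixed-image bins, computed over
  the overlap of the nonzero supports; least-squares is available for
  same-contrast problems. Optimization is coarse-to-fine over downsample
  factors 4, 2, 1 with a Nelder–Mead simplex at each level (at most 200
  iterations per level; simplex steps of 2 mm/°/% at the coarsest level
  down to 0.25 at full resolution; convergence tolerance 0.02 parameter
  units at full resolution). Initialization aligns intensity centers of
  mass, which removes gross offsets deterministically. The returned
  transform never scores worse than the starting one. On 64×64×40
  phantoms the suite recovers random rigid transforms drawn from ±5 mm /
  ±5° to better than 0.25 mm / 0.35° (bound asserted: 0.5 mm / 0.5°) and
  isotropic scale to well under 2%.
* **Interpolation** — nearest-neighbour for the FLAIR→T1 resampling and
  for all masks (labels must stay binary), trilinear for the
  normalization of intensity images (preserves the histogram that the
  threshold operates on). Out-of-field voxels are filled with 0, the
  value the statistics treat as background.
* **Smoothing** — separable Gaussian with per-axis
  σ_vox = FWHM / (2√(2 ln 2)) / spacing (FWHM 2 mm → σ = 0.849 mm);
  zero-padded borders, i.e. plain smoothing of a skull-stripped image.
  The background zeros are *not* compensated; a mask-normalized variant
  is available via `PreprocessConfig(mask_normalized_smoothing=True)`.

## Intensity statistics and thresholding

"All brain voxels" means the in-mask voxels when a mask is passed,
otherwise the strictly positive voxels — masking writes exact zeros, and
including them would drag μ down and inflate σ. The SD uses the sample
(N−1) denominator (configurable to N; at brain-size N the difference is
negligible but the convention is surfaced). A voxel exactly at the
threshold is lesion: the published rule excludes voxels *below* the
threshold, and keep-at-threshold matches common thresholding tools.
Thresholding is monotone in k by construction; this is property-tested.

Manual corrections are file-based binary masks, merged as
(lesion ∪ additions) \ removals with removals taking precedence on
overlap; the counts actually added and removed are kept as provenance.
Volumetry is exact voxel counting times the voxel volume (|det| of the
affine's 3×3 block, in mm³).

## Agreement evaluation

Dice similarity coefficient 2|A∩B|/(|A|+|B|); both-empty pairs are
defined as DSC = 1 (agreement on absence) with a logged warning, one
empty mask gives 0. Volume tables are compared with the paired
two-tailed Student's t-test (df = n−1), Pearson r (and r²), Spearman ρ
(Pearson on mid-ranks, ties averaged) and OLS regression with
F = (n−2)·r²/(1−r²) on (1, n−2) degrees of freedom. The regression is
reported as reference volume (x) against semi-automated volume (y); r
and r² are direction-invariant. Display rounding follows the field's
convention: 2 decimals for volumes and DSC, 3 for test statistics.

## The phantom generator

The phantom emulates the intensity structure the threshold model relies
on: a concentric-ellipsoid brain (CSF ventricles at 30, GM shell at 90,
WM core at 100 FLAIR units; T1 contrast reversed at 30/70/110), an
inferior block standing in for cerebellum + brainstem (flagged by the
exclusion mask), and ellipsoidal lesions stamped into WM at 160 —
12 noise-SDs above WM with the default noise SD of 5 (5% of the WM
mean). Gaussian noise is added to FLAIR and T1 only inside the head; the
zero background models the exact zeros of a skull-stripped image. Tissue
maps, masks and ground truth are noise-free and voxel-exact, so expected
counts are constructed, not estimated. The default lesion set is one
dominant confluent periventricular-type lesion plus a small deep lesion,
6.59 cm³ ≈ 3.6% of the phantom brain — the load fraction of a
moderate-to-high-burden subject. The template is the phantom's own
noise-free T1, so normalization is near-identity by default; stress
tests inject known transforms through `true_flair_to_t1` instead.

What the phantom does **not** emulate: Rician noise (at this SNR the
Gaussian approximation is excellent and keeps tail arithmetic
transparent), bias fields, partial-volume mixing beyond interpolation,
FLAIR-specific artifacts (septum pellucidum, fourth-ventricle flow), the
anisotropic 5-mm-slice geometry of 2-D FLAIR, and anatomical texture
within compartments. Passing the phantom suite therefore demonstrates
the pipeline's correctness and its noise/contrast behaviour, not its
accuracy on clinical images — that is what the shipped 30-subject
agreement tables quantify.

## Numerical choices and degenerate inputs

* Data are float32 internally regardless of on-disk type; affines are
  float64. NIfTI headers: sform is preferred when coded, then qform,
  then a spacing-only diagonal affine; files are written with both set.
* Constant images cannot be registered, fewer than two qualifying voxels
  yield no statistics, constant inputs yield no correlation, and paired
  series with zero difference variance yield no t-test — all raise
  explicit degenerate-input errors rather than NaNs.
* Registration non-convergence within the iteration budget logs a
  warning and returns the best transform found.
* A known bias of threshold segmentation after smoothing: the smoothed
  lesion edge crosses the threshold slightly *outside* the true
  boundary whenever the threshold sits below the edge midpoint, so the
  method over-segments by a sub-voxel shell. The effect scales with the
  lesion surface-to-volume ratio, which is why volume error is small for
  confluent lesions and proportionally larger for punctate ones.

## Validation problem sizes

The test suite runs the default 96×96×60 phantom once end-to-end and
uses 48×48×32 phantoms (with a proportionally small lesion) for the
repeated-pipeline suites, and 64×64×40 lesion-free phantoms for the
10-seed registration recovery — sizes at which the whole battery
completes in a few minutes while every geometric relationship of the
full phantom is preserved. `scripts/acceptance.py` uses the same sizes.

## Known limitations

Only linear (affine) spatial normalization is provided — no warp fields,
no bias-field correction, no DICOM or 4-D input. The single global
threshold cannot separate periventricular from deep lesions and is not a
tissue classifier; cohorts with very high lesion load violate assumption
2 above and shift the threshold upward. Manual editing is modelled as
deterministic mask merging; the package contains no interactive viewer.
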