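# wmhseg

Semi-automated segmentation of white matter hyperintensities (WMH) on
FLAIR MRI, with full validation machinery.

WMH are bright regions in cerebral white matter on T2-weighted / FLAIR
images, associated with small-vessel disease, mild cognitive impairment
and dementia risk. Quantifying their load matters clinically, but manual
tracing takes hours per subject and is rater-dependent. `wmhseg`
implements a transparent alternative built on a single global statistic
of the FLAIR intensity histogram, for neuroimaging researchers who want
reproducible lesion volumetry without training data or multi-spectral
acquisitions.

## Method

For each subject the pipeline:

1. **Pre-processes** the images: co-registers FLAIR to the T1-weighted
   image (affine registration, correlation-ratio cost), builds a binary
   brain mask as GM + WM + CSF from user-supplied tissue maps,
   skull-strips both images, registers the stripped T1 to a template and
   carries the FLAIR along, zeroes an exclusion mask covering cerebellum
   and brainstem (where WMH are rare), and smooths with a 2-mm FWHM
   Gaussian kernel.
2. **Segments** probable WMH by thresholding: with μ and σ the mean and
   standard deviation of all brain-voxel intensities, a voxel is lesion
   iff its intensity I satisfies

       I ≥ μ + k·σ,   k = 1.5 by default.

3. **Merges manual edits** as deterministic add/remove masks (removals
   win on overlap) and reports the lesion volume
   V = N_voxels · v_voxel / 1000 in cm³.

Agreement with reference segmentations is evaluated with the Dice
similarity coefficient,

    DSC(Seg, Ref) = 2·|Seg ∩ Ref| / (|Seg| + |Ref|),

(DSC ≥ 0.7 conventionally indicates good agreement) and with a
volume-table battery: paired Student's t-tests, Pearson/Spearman
correlation and ordinary least-squares regression. A synthetic phantom
generator provides FLAIR/T1 pairs with voxel-exact ground truth so every
stage is testable without any real MRI. See `docs/methods.md` for the
full model description and design choices.

## Worked example

Generate the default phantom (96×96×60 voxels at 1 mm, two white-matter
lesions totalling 6.59 cm³, Gaussian noise SD 5 on WM mean 100), run the
default pipeline, and score against the constructed ground truth:

```python
import wmhseg as w
from wmhseg.phantom import PhantomSpec, generate_phantom, score_against_truth
from wmhseg.preprocess import PreprocessConfig, preprocess_pipeline

b = generate_phantom(PhantomSpec(seed=1))
res = preprocess_pipeline(b.flair, b.t1, b.tissues, b.template,
                          b.exclusion_mask, PreprocessConfig())
seg = w.threshold_segment(res.flair, res.brain_mask, k=1.5)
score = score_against_truth(seg.lesion_map, b)
```

This prints (via the values on `seg` and `score`):

```
threshold  = 119.93  (mean 94.16 + 1.5 x SD 17.18)
lesion     = 7401 voxels = 7.401 cm^3
truth      = 6590 voxels = 6.590 cm^3
DSC = 0.942   FP = 813   FN = 2
```

The threshold lands between white matter (≈100) and the lesions (160),
the recovered volume is within 13% of truth, and the spatial overlap is
far above the 0.7 good-agreement bar. The residual false positives are a
thin shell around the lesion boundary created by smoothing.

The same stages are exposed as a CLI (`wmhseg phantom / preprocess /
segment / evaluate / run`). The agreement battery on the packaged
30-subject volume and DSC tables:

```bash
python -c "from importlib import resources
import shutil
for n in ('table1.csv','table2.csv'):
    shutil.copy(resources.files('wmhseg.data')/n, n)"
wmhseg evaluate --volumes table1.csv --dsc table2.csv
```

```
Agreement report  (n = 30 subjects)

Volumes (cm^3):
  rater1             mean  16.74  SD  13.89
  rater2             mean  19.50  SD  16.29
  semi_automated     mean  18.63  SD  14.81

Paired t-tests (a - b):
  rater1_vs_semi_automated         t =  -1.790  df = 29  p = 0.084
  rater2_vs_semi_automated         t =   1.113  df = 29  p = 0.275
  ...

Correlations:
  rater1_vs_semi_automated         r = 0.921  r^2 = 0.847  rho = 0.949
  rater2_vs_semi_automated         r = 0.967  r^2 = 0.935  rho = 0.970
  rater1_vs_rater2                 r = 0.976  r^2 = 0.952  rho = 0.976

Dice similarity coefficients:
  rater1_vs_rater2                 mean 0.81  SD 0.07
  rater1_vs_semi_automated         mean 0.78  SD 0.10
  rater2_vs_semi_automated         mean 0.77  SD 0.14
```

Neither manual rater differs significantly from the semi-automated
volumes, the correlations are high, and the mean DSC of ~0.78 against
both raters indicates good spatial agreement.

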