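# relimap

Test–retest reliability of repeated-measure 3D statistical images.

When the same statistical map (e.g., a task-fMRI contrast beta map) is
estimated for every subject on two or more occasions — two runs, or two
scanning sessions — the natural questions are: *how consistent is each voxel's
value across occasions*, *how much of the variance is stable between-subject
signal versus within-subject noise*, *how similar are the group maps*, and
*how many subjects does it take before these summaries stabilize*? `relimap`
answers all four for volumetric NIfTI data, and ships a synthetic-volume
generator with known ground truth so every stage can be exercised and
validated without any imaging download.

## The statistics

For `n` subjects and `k` occasions, a two-way ANOVA (one observation per
cell) gives mean squares MSBS (between subjects), MSBM (between occasions)
and MSError. The single-measure intraclass correlations are the
Shrout–Fleiss forms:

- **ICC(3,1)** (consistency, occasions fixed):
  `(MSBS − MSError) / (MSBS + (k−1)·MSError)` — for k = 2 this is
  `(MSBS − MSError)/(MSBS + MSError) = σ²_r / (σ²_r + σ²_v)`, the ratio of
  between-subject variance σ²_r to total variance;
- **ICC(2,1)** (absolute agreement, occasions random): adds
  `k(MSBM − MSError)/n` to the denominator, so a fixed per-occasion additive
  bias (a session effect) lowers agreement but not consistency;
- **ICC(1)** (one-way): uses the pooled within-subject mean square MSW.

Confidence bounds use the F statistic (Shrout–Fleiss pivots; the
McGraw–Wong Satterthwaite approximation for ICC(2,1)) rather than
bootstrapping. Voxel-wise application returns five 3D maps — estimate, lower
and upper bound, between-subject (BS) and within-subject (WS) variance —
plus the between-measure variance for ICC(2,1).

Group-map similarity is the Jaccard coefficient `|A∩B| / |A∪B|` (and Dice
`2|A∩B| / (|A|+|B|)`) on maps binarized at a threshold, or the Spearman rank
correlation of unthresholded maps. Sample-size stability bootstraps subjects
with replacement on a grid of n and tracks the 95% interval of the masked
median ICC/BS/WS across iterations. Specification-curve tools enumerate a
240-pipeline analytic grid (5 smoothing × 4 motion × 3 task-model × 4
contrast options; 360 with the full 6-option motion design) and order
per-pipeline estimates with across-sample intervals and significance classes.

## Worked example

Five subjects, two occasions, occasion B exactly 3× occasion A
(`examples/01_scalar_icc.py`):

```
occasion A = (1.0, 3.0, 6.0, 9.0, 12.0)
occasion B = (3.0, 9.0, 18.0, 27.0, 36.0)
MSBS = 157.6, MSBM = 384.4, MSError = 39.4
Pearson r between occasions: 1.00
icc_1: 0.185  (95% CI -0.671 .. 0.863)
icc_2: 0.353  (95% CI -0.156 .. 0.876)
icc_3: 0.600  (95% CI -0.412 .. 0.949)
```

The occasions are perfectly correlated, yet ICC(3,1) = 0.60: tripling the
scores triples the spread, so only 60% of the total variance is stable
between-subject signal. ICC(2,1) is lower still because absolute agreement
also charges the occasion-mean difference; with n = 5 the F-based bounds are
wide.

The same computation voxel-wise, on simulated volumes whose every voxel has
σ²_r = 3, σ²_v = 2 (true ICC 0.6; `examples/02_voxelwise_reliability.py`):

```
masked median estimate: 0.589
masked median between_subject_var: 2.964
masked median within_subject_var: 2.034
```

Library quick start:

```python
from relimap import MeasurementMatrix, icc
m = MeasurementMatrix.from_occasions([[1, 3, 6, 9, 12], [3, 9, 18, 27, 36]])
print(icc(m, "icc_3").estimate)   # 0.6
```

See `examples/` for map similarity, stability curves and specification
curves, and `docs/methods.md` for the modeling details. A thin CLI
(`relimap icc|similarity|stability|simulate|speccurve`) wraps the library
for shell use; inputs are explicit ordered TSV manifests so subject pairing
across occasions stays auditable.

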