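# Methods

## Model

All reliability estimates derive from the additive random-effects model for a
measure `y_ij` of subject `i = 1..n` on occasion `j = 1..k` (applied
independently at every voxel of a 3D volume):

```
y_ij = mu + b_i + s_j + e_ij ,   b_i ~ N(0, sigma2_r),  e_ij ~ N(0, sigma2_v)
```

with `s_j` a fixed per-occasion additive bias (session/practice effect). The
two-way ANOVA with one observation per cell yields MSBS, MSBM and MSError
with degrees of freedom `n−1`, `k−1` and `(n−1)(k−1)`; the one-way fit pools
occasion and residual variation into MSW with `n(k−1)` df. Sums of squares
are computed from centered sums in double precision (never by subtraction),
so each term is nonnegative and the partition
`SS_subject + SS_measure + SS_error = SS_total` holds to rounding error.

Moment estimators of the components: `sigma2_r = (MSBS − MSError)/k`
(negative values are *not* truncated — small true ICCs routinely produce
them, and truncation would bias medians over voxels), `sigma2_v = MSError`,
and for the random-occasion model `sigma2_m = (MSBM − MSError)/n`, also
propagated raw when negative.

ICC forms (single measure, general k): ICC(3,1) =
`(MSBS − MSError)/(MSBS + (k−1) MSError)`; ICC(2,1) adds
`k(MSBM − MSError)/n` to the denominator; ICC(1) substitutes MSW. The code
implements the general-k forms; a unit test verifies that at k = 2 ICC(3,1)
coincides with `(MSBS − MSError)/(MSBS + MSError)` and with
`sigma2_r/(sigma2_r + sigma2_v)` to 1e-12 relative.

## Confidence bounds

Two-sided F-based bounds at level `1 − alpha` (default alpha = 0.05):

- ICC(3,1): with `F = MSBS/MSError`, `FL = F / F_{1−a/2}(n−1, (n−1)(k−1))`,
  `FU = F · F_{1−a/2}((n−1)(k−1), n−1)`, bounds `(F* − 1)/(F* + k − 1)`.
- ICC(1): same pivot with MSW and df `n(k−1)`.
- ICC(2,1): the McGraw & Wong (1996) Satterthwaite degrees of freedom for the
  denominator mixture; the implementation is cross-checked in the test suite
  against `pingouin.intraclass_corr` (agreement to pingouin's printed
  precision), which serves strictly as an oracle, never as the
  implementation.

Conventions at the edges: zero error variance with nonzero subject spread
(perfect consistency) returns bounds (1, 1); zero total variance returns a
NaN estimate and bounds with an explicit `degenerate` flag, so voxel maps
carry a quiet missing value instead of a fabricated 0 or 1. Bounds are
clipped to contain the point estimate, which only matters in the extreme
`alpha → 1` limit where the quantile pivots cross the estimate.

## Voxel-wise application

`voxelwise_icc` reshapes the masked data to `(n, k, V)` and evaluates the
same kernels in one vectorised pass; a property test asserts per-voxel
equality with the scalar path on random volume sets. Maps outside the mask
and at degenerate voxels are NaN in all outputs; medians and similarity
metrics skip NaN. Volumes are matched by list order (manifest order), never
by filename parsing.

Thresholding for binary similarity is strictly `value > threshold`,
one-sided on positive values (activation maps are thresholded on the
positive tail; negative tails are not binarized). A threshold of exactly 0
selects *every* in-mask voxel, so two maps binarized at 0 always have
similarity 1 — a deliberate convention, useful as a degenerate control.
Spearman uses average ranks for ties (scipy's `spearmanr`). An empty union
(Jaccard/Dice) or zero rank variance yields a NaN coefficient with an
explanatory note, not an exception.

## Bootstrap stability

`subsample_stability` draws subjects **with replacement**, paired across
occasions (the only scheme that preserves within-subject structure), for
each n on a grid (default 25..525 step 50, 100 iterations — the
consortium-scale defaults; tests and examples use smaller grids). A subject
drawn twice contributes two identical rows, which biases BS slightly
downward relative to subsampling without replacement; this is documented
behavior, not a bug. The 95% interval per n is the 2.5/97.5 empirical
percentile across iterations. RNG: one substream per `(n, iteration)` via
`SeedSequence(entropy=seed, spawn_key=(n, it))`, so extending the grid never
changes draws already taken. Confidence-bound maps are skipped inside the
loop (only medians of estimate/BS/WS are needed), which keeps the loop cost
at one vectorised ANOVA per draw.

## Multiverse aggregation

The decision vocabulary is frozen: FWHM `{1.5x, 2x, 2.5x, 3x, 3.5x}` (voxel
multiples), motion `{none, reg, reg+acompcor, reg+acompcor+censor}` (the full
design adds two mean-FD exclusion variants), model `{CueMod, FixMod,
AntMod}`, contrast `{LgainNeut, LgainBase, SgainNeut, SgainBase}` — 240
combinations, 360 with the full motion grid. First-level GLM execution for
these pipelines is out of scope; the module consumes per-pipeline summary
estimates.

The specification curve uses the across-sample mean per pipeline with a 95%
t-interval (`mean ± t_{.975, s−1}·SE`; chosen because the typical
across-sample count is tiny, e.g. 3, where a normal interval would be
anticonservative; a single sample degenerates to the point estimate).
Pipelines sort ascending by mean with lexicographic option-label
tie-breaking so the curve is bit-reproducible. Significance versus the null
(0 for ICC curves): gray when the interval spans the null, blue above, red
below. `summarize_multiverse` stratifies masked medians by disjoint supra-
and subthreshold masks (overlap is an error).

## Synthetic data

The generator draws exactly the model above, per voxel, with scalar or
map-valued `sigma2_r`, `sigma2_v` and grand mean, fixed occasion biases, and
a seeded brain-mask fraction; the implied true maps (ICC(3,1) =
`sigma2_r/(sigma2_r + sigma2_v)`, BS, WS) are returned alongside the
volumes. Supra-/subthreshold masks are a seeded random split of the in-brain
voxels — a stand-in for thresholding an independent meta-analytic map.

What it emulates: the subject × occasion variance structure, occasion
(session) biases, and optional spatial autocorrelation via
variance-preserving Gaussian smoothing with periodic boundaries (every voxel
keeps the nominal marginal variance exactly). What it does not: BOLD
timeseries, hemodynamics, task event structure, motion artifacts,
non-Gaussian tails, or realistic anatomy. Passing recovery tests therefore
validates the estimators under their own assumptions, not the full
measurement chain of real imaging data.

Default conditions used by the validation suite: k = 2 occasions; recovery
runs at n = 150 subjects over 50 seeds on an 8×8×8 grid with mask fraction
0.75 (≈384 voxels — enough for stable medians while keeping the whole suite
in seconds); Monte-Carlo stability checks at n up to 150 with grids around
(25..150) and 15–50 iterations. Gaussian effects were chosen because the
ANOVA/ICC framework assumes them implicitly; a heavy-tailed option is
deferred.

## Numerical and design choices

- Double precision throughout; mask binarization is `value > 0` on load.
- Grid equality requires identical shapes and affines within 1e-4 absolute.
- Manifests are explicit ordered TSVs (`subject`, `occasion`, `path`), not
  glob patterns, so subject pairing is auditable; tables are UTF-8 TSV with
  `NA` for missing.
- Fixed-effects averaging of run-level estimates is the inverse-variance
  (precision-weighted) formula `beta = Σ(b/v)/Σ(1/v)`, `var = 1/Σ(1/v)`.
- Design efficiency of a GLM contrast is `1/(c (X'X)^{-1} c')`; a
  rank-deficient design raises a specific error rather than pseudo-inverting.
- `t_to_cohens_d` implements `d = t/√N` for converting group t-maps to
  effect-size maps before thresholding.

## Known limitations

ICC variants beyond (1), (2,1), (3,1) (no average-measure ICC(·,k)); no
surface (GIFTI/CIFTI) support; no cluster-extent thresholding or
permutation inference; similarity binarization ignores negative tails by
design; the ICC(2,1) interval is an approximation whose exactness degrades
at very small n and extreme ICCs.
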