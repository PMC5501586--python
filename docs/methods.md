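# Methods

`ctdnacnv` is an in-silico evaluation of copy-number-based cancer screening
from cell-free DNA (cfDNA). It has four scientific parts: a count model for
shallow whole-genome cfDNA sequencing, a theoretical limit-of-detection (LOD)
calculator built on that model, a conversion of tumor copy-number
segmentations into the coarse profiles a cfDNA assay could actually see, and
classifiers that ask whether such profiles identify cancer and its tissue of
origin. A synthetic-data module generates every input with known ground
truth.

## cfDNA count model

Reads from shallow WGS are counted in adjacent 10 kb bins. Three artifacts
dominate raw bin counts: mismapping-prone regions with grossly inflated
counts, a smooth multiplicative dependence on GC fraction, and library-size
differences between donors. The preprocessing chain handles them in order:

1. **Outlier masking.** Each bin is one observation whose coordinates are its
   counts across donors. A Minimum Covariance Determinant (MCD) estimator
   (h-subset with support fraction 0.75) gives a robust location and scatter;
   the scatter uses the raw h-subset covariance with the chi-squared-median
   consistency factor. Bins whose Mahalanobis distance exceeds 15 are masked.
   The joint (multivariate) formulation is used because a single distance per
   bin is wanted; artifact bins are inflated in every donor, which is exactly
   the direction the joint estimator flags.
2. **GC correction.** Per donor, a LOESS regression (span 0.3) of count on GC
   over usable bins estimates the expected count `c(gc)`; corrected counts
   are `round(raw · M / c(gc))` with `M` the grand mean count over all usable
   bins *and donors*. Normalising to a common target deliberately also
   equalises library sizes, so the corrected counts of all donors pool into
   one count distribution for the model fit. Counts are re-rounded to
   integers so downstream fits remain count models.
3. **Model fit.** A negative binomial with pmf
   `P(X=k) = (r/(r+m))^r · Γ(r+k)/(k!·Γ(r)) · (m/(r+m))^k`
   (mean `m`, dispersion `r`, variance `m + m²/r`) is fitted by maximum
   likelihood: `m̂` is the sample mean; `r̂` maximises the profile likelihood
   starting from the method-of-moments value `m²/(var − m)`. A Poisson fit by
   mean is reported alongside, and a Pearson chi-squared test over
   equal-probability count cells (cells merged until expected ≥ 5;
   df = cells − params − 1) compares the two. Underdispersed inputs cap `r`
   at 10⁸ (numerically Poisson) with a warning rather than failing.

Depth subsampling is binomial thinning. Thinning an NB(m, r) count at rate p
gives NB(p·m, r) — the dispersion is depth-invariant — which is what lets a
model fitted at one depth be rescaled to any other.

## Limit of detection

A CNV of length L is treated as a single super-bin. Because a sum of n i.i.d.
NB(m, r) variables with common success probability is NB(n·m, n·r), a region
spanning n bins has baseline total NB(M0, R) with `M0 = d·L/ℓ` reads (depth
d, read length ℓ) and `R = r·L/bin_size`. cfDNA from a carrier is a linear
tumor/normal mixture, so a tumor copy change Δc present at ctDNA fraction f
shifts the expectation to `M1 = M0·(1 + f·Δc/2)`. The detection p-value is
the right tail of the baseline NB at ⌈M1⌉ for gains (left tail at ⌊M1⌋ for
losses — gains-only in the source analysis; the loss rule is the symmetric
extension), with detection declared below 0.01. The minimal detectable size
scans a 1 Mb-step grid (1–250 Mb by default; 1 Mb matches the smallest focal
amplification scale of interest).

Two numerical notes. Tails are computed through the scipy NB survival
function (log-space internally); and for large expected counts
(M0 ≥ 10⁴) the whole construction collapses to the normal-approximation
closed form `L* = z² (ℓ/d + bin/r) / (f·Δc/2)²`, which the tests use as an
independent oracle — agreement is within one grid step across the default
operating range.

## Detectable copy profiles

Tumor segmentations (SEG files; `Segment_Mean` read as log2(copy/2) and
converted via `copies = 2·2^value`) are reduced to what a cfDNA assay could
see on a fixed 5 Mb or 100 Mb genome grid:

* **Germline filter.** Records with reciprocal overlap ≥ 0.5 against a
  population CNV of allele frequency > 1% are removed (a generic interval
  filter; no annotation pipeline).
* **Average deviation.** Per grid segment, the length-weighted mean of
  (copies − 2); uncovered basepairs are diploid. Overlapping records within
  a sample are resolved with later-record precedence and a warning.
* **Detectability.** `|avg_dev| ≥ 1`: one full average copy gained or lost.
  So a 1 Mb event of +5 copies in a 5 Mb segment (average +1) and a whole
  segment gained once are both detectable; the threshold is inclusive, and
  applied symmetrically to losses.
* **Five copy states.** avg_dev is discretized to
  {2-copy loss, 1-copy loss, near-normal, 1-copy gain, ≥2-copy gain} with
  breakpoints at ±0.5 and ±1.5 — rounding to the nearest integer copy state.
  Gaussian-quantile SAX breakpoints are deliberately not used: the
  categories are copy-count-semantic, not distribution-quantile-semantic.
  All segments are categorised; the detectable flag is kept separately.

## Classification

* **Distance.** Per segment: 0 for equal states, 0.5 for adjacent states in
  the ordered five-state alphabet, 1 otherwise; summed over segments. This
  is a metric (verified exhaustively over all 125 state triples).
* **KNN.** Leave-one-out: each sample is voted on by its k = ⌊√N⌋ nearest
  other samples; ties break by the smaller summed distance to the tied
  class, then lexicographically (deterministic).
* **Hierarchical clustering.** Average linkage on the distance matrix,
  optionally restricted to the segments the forest finds informative
  (unfiltered profiles cluster poorly; informative-segment clustering is the
  interesting view). Linkage is configurable.
* **Random forest.** 100 trees, stratified 10-fold CV; states enter as
  ordered integers (−2…+2) rather than one-hot because they are ordinal. The
  split-candidate count is chosen heuristically among {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋}
  by CV accuracy. Reports pool out-of-fold predictions and probabilities
  (every sample predicted exactly once); importances are impurity-based from
  a full-data fit with the winning setting.
* **Metrics.** Per-class TPR and PPV (PPV is NA for never-predicted
  classes), overall accuracy ± SD across folds, one-vs-rest ROC curves with
  the operating point nearest (FPR 0, TPR 1), and the pairwise
  misclassification similarity `S(A,B) = (α+β)(A_n+B_n)/N`, with types
  ordered for display by average-linkage clustering on `max(S) − S`.

## Synthetic data: what it emulates, what it does not

`gen_healthy_bincounts` draws counts NB(mean·bias(gc)·s_j, r) per bin/donor:

* `mean_per_bin` 300, `dispersion` 50 — roughly 3× haploid coverage of 100 bp
  reads with moderate overdispersion; 200,000 bins, 9 donors.
* GC fractions ~ Beta(8.2, 11.8) (mean 0.41, sd ≈ 0.11); the bias curve is a
  quadratic peaking near the GC mode with ±30% amplitude, normalised to mean
  one over the GC distribution so it does not shift the genome-wide mean.
* library-size factors s_j are log-normal with σ = 0.05 — this forces the
  preprocessing to normalise across donors.
* 1% of bins have their mean inflated 10-fold in every donor (mismapping
  proxy); ground-truth indices are returned.

`spike_cnv` redraws the counts of a region from the stored recipe with the
mean scaled by `1 + f·Δc/2`; it therefore requires a table that carries its
generation recipe. `gen_tumor_cohort` realises per-type recurrent events
(Bernoulli per event, whole grid segments) plus Poisson passenger events;
`separable_signatures` builds the disjoint probability-1 signatures used in
recovery tests (default: 2 segments per type at +2 copies, passenger rate
0.5). The germline generator emits random intervals with uniform allele
frequencies and the ground truth of which exceed 1%.

Not emulated: raw reads, fragment-length or end-motif biology, sequencing
error, subclonal heterogeneity, segmentation noise (events align to grid
segments), wavy genomic coverage, and real recurrence patterns of specific
cancer types. Passing tests therefore demonstrate correctness of the
*method* under its stated model, not clinical performance; headline numbers
from real cohorts (e.g. per-type TPR/PPV against TCGA-derived profiles) are
out of reach of synthetic signatures by construction.

## Numerical and design choices

* Internal coordinates are 0-based half-open; SEG on disk is 1-based
  inclusive; conversions live only in the IO layer.
* The synthetic genome is a plain linear coordinate system split into named
  pseudo-chromosomes; no reference genome is used anywhere.
* MCD distances come from the *raw* (pre-reweighting) estimates, consistent
  with flagging by a fixed distance cut; the estimator is seeded, so masking
  is reproducible.
* LOESS prediction interpolates the fitted curve at each bin's GC; the fit
  uses a delta of 0.5% of the GC range for speed at 200k bins.
* Detection evaluates the tail at the integer ceiling (gains) / floor
  (losses) of M1.
* Region aggregation vs. rescaling a single bin's model to region size both
  give size-dependent power; aggregation (super-bin with R = r·n_bins) is
  used because it is the closure rule consistent with the NB sum identity.
* The dispersion at reduced depth is obtained by refitting thinned counts
  (the thinning closure makes the refit a consistency check, not new
  information).
* Pipeline defaults are desk-scale (20k bins, 5 types × 40 + 80 normal on a
  1.2 Gb pseudo-genome at 5 Mb resolution); every size is a config field.

## Known limitations

* The detectability threshold and breakpoints are copy-semantic constants;
  no data-driven calibration is attempted.
* KNN uses full category vectors over all segments; no feature selection.
* The forest's split-candidate search uses the same folds for selection and
  reporting, which can be slightly optimistic; with three candidates the
  effect is negligible for the recovery checks performed here.
* Losses in the LOD engine use a symmetric rule that the gains-only source
  analysis never exercised.
* `spike_cnv` operates on the generation recipe, so it cannot spike real
  (non-synthetic) count tables; spiking real data would require an
  over-dispersion-preserving resampling scheme instead.
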