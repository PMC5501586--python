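# ctdnacnv

An in-silico assessment of cancer screening from copy-number variants (CNVs)
in circulating tumor DNA (ctDNA). The package is a library (plus a thin
`ctdnacnv` command line) for researchers who want to reason quantitatively
about shallow whole-genome cfDNA sequencing as a screening assay: how deep to
sequence, how small a CNV is visible at a given tumor fraction, and how much
cancer-type information survives at the coarse resolution such an assay
provides.

## What it computes

**Count model.** Reads in adjacent 10 kb genome bins are modelled as negative
binomial after masking artifact bins (robust Minimum Covariance Determinant
Mahalanobis distance > 15) and LOESS GC correction:

    P(X = k) = (r/(r+m))^r · Γ(r+k)/(k!·Γ(r)) · (m/(r+m))^k,
    Var(X) = m + m²/r.

**Limit of detection.** A CNV of length L at ctDNA fraction f and copy change
Δc shifts the expected read count of the region from M0 = d·L/ℓ to
M1 = M0·(1 + f·Δc/2); the region total is NB(M0, R) with R = r·L/bin. The
detection p-value is the NB tail at ⌈M1⌉ and the LOD is the smallest L (1 Mb
grid) with p < 0.01.

**Detectable profiles.** Tumor segmentations (SEG) are reduced to 5 Mb or
100 Mb grid profiles: germline CNVs (population allele frequency > 1%)
filtered, length-weighted average copy deviation per segment, detectable when
|avg| ≥ 1 extra copy, and discretized to five ordered copy states.

**Classification.** A modified Hamming distance on the copy states (adjacent
states cost 0.5, distant ones 1) feeds leave-one-out KNN with k = ⌊√N⌋ and
hierarchical clustering; a 100-tree random forest with stratified 10-fold CV
provides the (near-)optimal reference, per-class TPR/PPV, ROC operating
points nearest (0, 1), and a misclassification similarity
S(A,B) = (α+β)(A_n+B_n)/N between cancer types.

All inputs can be generated synthetically with known ground truth
(`ctdnacnv.synthdata`), which is how the test suite validates parameter
recovery end to end. See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
import ctdnacnv as c

params = c.HealthySimParams(n_bins=50_000, n_samples=9, seed=7)
sim = c.gen_healthy_bincounts(params)                 # synthetic healthy cfDNA
masked, _ = c.mcd_outlier_mask(sim.table)             # distance > 15 masked
corrected = c.gc_correct(masked)                      # LOESS GC normalisation
nb, pois, diag = c.fit_count_model(corrected)
stat, p = c.gof_chisq(corrected, nb)
print(f"masked {int((~masked.mask).sum())} of {sim.table.n_bins} bins")
print(f"NB fit: m = {nb.m:.1f}, r = {nb.r:.1f}  (depth {nb.depth:.2f}x)")
print(f"chi-squared GOF vs NB: p = {p:.2f}")
for f in (0.10, 0.01, 0.005):
    size = c.min_detectable_size(3.0, f, 1, nb)
    print(f"LOD at 3x depth, {f:.1%} ctDNA, +1 copy: {size/1e6:.0f} Mb")
size4 = c.min_detectable_size(3.0, 0.005, 4, nb)
print(f"LOD at 3x depth, 0.5% ctDNA, +4 copies: {size4/1e6:.0f} Mb")
```

prints

```
masked 500 of 50000 bins
NB fit: m = 308.5, r = 50.0  (depth 3.08x)
chi-squared GOF vs NB: p = 0.02
LOD at 3x depth, 10.0% ctDNA, +1 copy: 1 Mb
LOD at 3x depth, 1.0% ctDNA, +1 copy: 51 Mb
LOD at 3x depth, 0.5% ctDNA, +1 copy: 203 Mb
LOD at 3x depth, 0.5% ctDNA, +4 copies: 13 Mb
```

Reading the numbers: all 500 planted artifact bins (1% of the genome) are
masked; the refit recovers the generating dispersion r = 50 and the mean
within ~3% (the realized library-size spread of the nine donors). The GOF
p-value of 0.02 illustrates how sensitive a chi-squared over ~450k pooled
counts is — integer re-rounding during GC correction alone is visible at
this sample size. The LOD table shows the central trade-off: at 10% tumor
fraction even 1 Mb focal amplifications are easy at 3× coverage, at 1% only
~50 Mb events are visible, at 0.5% only chromosome-arm-scale changes —
unless the region is highly amplified (+4 copies), which pulls the limit
down to ~13 Mb.

The `examples/` directory holds one short script per capability (count model
fitting, LOD curves, detectable profiles, classification, full pipeline);
each prints its results with a line on what they mean. The same stages are
available from the shell:

```bash
ctdnacnv run-all --out run1 --seed 3
```

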