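# peaknorm

Quantitative normalization and comparison of two ChIP-seq samples.

Comparing ChIP-seq signal across cell types or conditions is confounded by
differences in sequencing depth and signal-to-noise ratio between
libraries.  Genome-wide normalizations (total-read scaling, quantile
matching) assume the *global* read distribution is invariant, which fails
precisely when binding genuinely differs.  `peaknorm` instead normalizes on
**common peaks** — peaks called in both samples — under the weaker
assumption that the true binding at most shared sites is unchanged, then
quantifies differential binding at every peak.

## Model

For each peak, reads are counted in a fixed window (default 2,000 bp for
histone marks, 1,000 bp for transcription factors) centered at the summit.
With raw counts *x₁*, *x₂* and a +1 pseudocount:

```
M = log2((x1 + 1) / (x2 + 1))          # log2 fold change
A = log2((x1 + 1)(x2 + 1)) / 2         # mean log2 intensity
```

Peaks overlapping (≥ 1 nt, or summit-within-distance) a peak of the other
sample are *common*; each is paired with the partner of smallest
summit-to-summit distance.  Robust regression (iteratively reweighted least
squares with Tukey bisquare weights, c = 4.685) fits

```
M = a + b·A
```

to the common-peak pairs; the bisquare weights zero out genuinely
differential common peaks so the line captures only the global bias.  A
coordinate transformation then maps this line onto M = 0 for **all** peaks,
yielding normalized M, A and read densities.  Each peak's differential
significance is an Audic–Claverie P-value: conditional on n = x + y, the
normalized count y is Binomial(n, ½), and the reported P is the two-sided
exact tail.  Peaks are called sample-biased when |M_norm| ≥ m-cutoff
(default 1) **and** P ≤ p-cutoff (default 0.01).

Downstream modules map peaks to promoters (−8 kb/+2 kb of the TSS) and
score M-binned enrichment against differentially-expressed gene lists;
scan JASPAR position-weight matrices over summit windows and cluster motif
scores with M (Ward linkage on 1 − ρ) to nominate cell-type-specific
regulators; and provide the three genome-wide baseline normalizations
(total reads, bin quantile, genome-wide MA + LOWESS) for comparison.

## Worked example

No real data needed — the package ships a generator that simulates a
two-sample experiment with known ground truth (here: 500 common peaks, a
4-fold library ratio, 10% of common peaks with a true 4-fold binding
change):

```
$ peaknorm simulate --n-common 500 --seed 7 --output-dir demo/sim
wrote 650 + 650 peaks and 416479 + 91943 tags to demo/sim

$ peaknorm run --peaks1 demo/sim/peaks1.bed --peaks2 demo/sim/peaks2.bed \
               --reads1 demo/sim/tags1.bed  --reads2 demo/sim/tags2.bed \
               --name1 ES --name2 K562 --output-dir demo/out
fitted M = 2.0108 + -0.0016 * A on 500 common-peak pairs (converged=True)
peaks: 241 ES-biased, 143 K562-biased, 916 unbiased
outputs written to demo/out
```

The fitted intercept 2.01 recovers the simulated log2 library ratio
(log2 4 = 2) and the near-zero slope shows no intensity-dependent bias.
The ES-biased calls comprise the sample-1-unique peaks plus the planted
true-positive common peaks; the output directory contains the all-peaks
TSV (normalized M/A, densities, P-value, class per peak), one BED file per
class, one WIG track of normalized M per sample for genome-browser
display, before/after MA plots, and a JSON manifest of the fit.

The same pipeline is available as a library:

```python
from peaknorm import RunConfig, run_manorm
result = run_manorm(RunConfig(peaks1="p1.bed", peaks2="p2.bed",
                              reads1="t1.bed", reads2="t2.bed"))
result.model       # LinearModel(a=..., b=..., n_points=..., converged=True)
result.table       # per-peak DataFrame
```

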