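# Methods

## The normalization model

Two ChIP-seq libraries of the same target differ in sequencing depth and in
immunoprecipitation efficiency (signal-to-noise).  Both act, to first
order, as a multiplicative distortion of the read density a peak would show
in the other sample — plus, possibly, an intensity-dependent component.  In
MA coordinates (M = log2 density ratio, A = mean log2 density, both with a
+1 pseudocount on window counts) a pure multiplicative offset is a
horizontal line M = a and an intensity-dependent bias a tilted line
M = a + b·A.

The key assumption is biological, not technical: **most peaks present in
both samples have unchanged true binding**.  The line is therefore fitted
only to common-peak pairs, with Tukey-bisquare IRLS so that the minority of
genuinely changed common peaks — which appear as M outliers — receive zero
weight and do not bias the fit.  Unique peaks, which legitimately have
extreme M, never enter the fit but are normalized by the same model.

### Pairing

A peak is common if it overlaps (≥ 1 nt) a peak of the other sample, or,
in summit mode, if some other-sample summit lies within a cutoff (500 bp
histone / 250 bp TF defaults).  When several candidates qualify, the
partner with the smallest summit-to-summit distance is chosen (ties:
smaller start, then input order — determinism matters for reproducible
fits).  The pair list used for fitting is the deduplicated union of
nearest-partner links from *both* samples' perspectives, and each pair's
(M, A) is computed in a window centered at the midpoint of the two
summits.  Both choices make the procedure exactly symmetric: swapping the
two input samples negates the fitted (a, b) and every normalized M, and
leaves every P-value unchanged.  (One-sided linking would break this
whenever links are many-to-one.)

### Read counting

Each read is reduced to its strand-aware 5′ coordinate shifted 100 bp
3′-ward (≈ half a ChIP fragment; exposed as `--shift`) and counted in a
half-open window [summit − w/2, summit + w/2).  Window width should match
the median enriched-region length: 2,000 bp for histone marks, 1,000 bp
for transcription factors.  Counts are carried forward, not per-bp
densities: at fixed width they are proportional, and the pseudocount is
defined on counts.

### The robust fit

IRLS on M vs A over the pairs: ordinary least squares initialization; each
iteration computes residuals, a scale of 1.4826 × MAD (floored at 1e-8 so
an exact fit does not divide by zero), bisquare weights
w = (1 − u²)² for u = r/(4.685·scale) (zero beyond |u| = 1), and a weighted
least-squares solve; convergence when the largest coefficient change is
below 1e-8, capped at 50 iterations.  c = 4.685 gives 95% efficiency under
Gaussian noise while rejecting gross outliers.  Fewer than 2 pairs, or no
spread in A, is an error rather than a silent fallback.

### Normalization

Two modes, both mapping the fitted line to M_norm = 0:

- **rescale** (default): sample 2 is the anchor; sample 1's log density is
  rescaled as t1′ = ((2 − b)·t1 − 2a)/(2 + b), t2′ = t2.  This is the
  unique affine map of t1 alone with that property, and it yields the
  closed-form identity M_norm = 2(M − a − b·A)/(2 + b).  It requires
  |b| < 2; a steeper fit raises an error directing the user to residual
  mode rather than producing a sign-flipped transform.
- **residual**: the correction a + b·A is split evenly between the
  samples, t1′ = t1 − (a + b·A)/2 and t2′ = t2 + (a + b·A)/2, so
  M_norm = M − a − b·A and A_norm = A.  This mode is exactly antisymmetric
  under sample swap and keeps normalized densities defined for the
  P-value.

Normalized densities are d = 2^t′ on the pseudocount scale.  Refitting the
robust line on residual-mode normalized pairs returns the zero line to
numerical precision; in rescale mode A_norm mixes a small b-dependent
multiple of M into the abscissa, so the refit is only near-zero (exact at
b = 0) — one reason residual mode is offered.

### Differential significance

The Audic–Claverie model compares two counts of the same region across
libraries: the point kernel p(y|x) = (x+y)!/(x!·y!·2^(x+y+1)) implies that,
conditional on n = x + y, y ~ Binomial(n, ½).  The normalized counts are
x = max(0, round(d1 − 1)), y = max(0, round(d2 − 1)) (the pseudocount is
undone before testing).  The reported P is the two-sided exact tail:
twice the smaller of P[Bin(n,½) ≤ y] and P[Bin(n,½) ≥ y], each tail
including the observed point, capped at 1.  Both tails are evaluated as
lower-tail log-sum-exp sums (the upper tail via the pmf symmetry
P[≥ y] = P[≤ x]), which makes the value exactly symmetric in (x, y).
Doubling the smaller tail was chosen over summing "as-or-more-extreme"
point masses; with a symmetric Binomial(n, ½) null the two differ only in
how the observed atom is shared, and doubling is the conservative,
simpler-to-characterize convention.

A peak is called sample-1-biased when M_norm ≥ m-cutoff and P ≤ p-cutoff
(mirrored for sample 2); defaults m = 1, P = 0.01.  When read densities
are high, |M| ≥ 1 alone is typically significant; at low densities the
combined cutoff protects against calling noise.

## Target genes and enrichment

A peak targets a gene when its summit lies in the strand-aware promoter
window, TSS − 8 kb to TSS + 2 kb (mirrored on the − strand).  A gene with
several targeting peaks takes the M of the peak nearest its TSS (tie:
larger A — the better-measured peak).  Genes are binned by integer M from
−4 to 4 with open-ended outer bins; bins under 50 genes are merged,
smallest first, into the larger neighbor (tie: the neighbor nearer M = 0)
— small bins otherwise produce extreme ratios.  Enrichment of a bin G
against a DE list D in universe U is (|G∩D|/|G|)/(|D|/|U|); the whole
universe as one bin scores exactly 1, and permuted M assignments score ≈ 1
in every bin.

## Motif analysis

Background nucleotide frequencies come from 10,000 random 1,000-bp genome
segments (uniform with replacement, segments > 50% N skipped, ε = 1e-3
regularization so all four frequencies are positive).  A PWM is scanned
over both strands of a summit-centered window; the raw score is the best
Σ log2(p_motif/p_background) over all offsets (log base 2 throughout — a
convention, since only ratios of scores matter; N positions contribute 0).
The motif score is raw/consensus, where the consensus score sums each
position's maximum log-odds, so score 1 ⇔ the consensus occurs.  JASPAR
count matrices get a +0.8 total pseudocount split by background, and every
probability matrix a 1e-3 per-cell floor, keeping log-odds finite.

Motif enrichment in peaks over the same random background segments uses a
presence threshold (normalized score ≥ 0.7, exposed — the "present" notion
has no canonical value), a one-sided Fisher exact test with Bonferroni
correction over the motifs tested, and an enrichment-score filter
(ES > 1.2, corrected P < 1e-5 by default).  Retained motifs' per-peak
scores are clustered with the peaks' M values (or −M for the other
sample's peaks) by Ward linkage on 1 − Pearson ρ; motifs adjacent to M in
the dendrogram, equivalently with the highest ρ, are the candidate
drivers of the sample-specific binding.

## Baselines

For comparison, three genome-wide normalizations over non-overlapping bins
of the counting-window width: (1) total-read scaling of pseudocounted peak
counts; (2) quantile matching of per-bin counts — each sample's k-th order
statistic becomes the mean of the two k-th order statistics, with tied
counts assigned consecutive order-statistic means in stable order so the
two normalized distributions are *identical* as multisets (tie-averaging
would break that exactness for count data, which is full of ties);
(3) genome-wide MA with LOWESS trend removal (tricube weights, fraction
0.3, 2 robustifying iterations) over non-empty bins.  Peak-level baseline
values are projected from the bin containing the peak summit.

## The synthetic-data generator

`simulate.SimulationConfig` defaults define the study conditions: 1,000
common peaks plus 150 unique peaks per sample on a 2 × 10 Mb genome;
per-peak sample-2 mean window counts λ ~ LogNormal(μ = 4, σ = 0.8)
(median ≈ 55 tags — typical well-powered peaks with a realistic heavy
right tail); a global 4-fold library ratio `scale_c` applied to *all* of
sample 1's signal including its background (scale_c models a
depth/efficiency ratio, which is exactly the distortion the method is
built to remove); background 2 tags/kb in sample 2; 10% of common peaks
carry a true log2 effect of 2 in sample 1.  Tag counts are Poisson around
each λ; positions are Gaussian (σ = 150 bp) around the summit and
strand-split ±100 bp so the default 100-bp shift re-centers them; unique
peaks have signal in one sample only; common summits are jittered ≤ 50 bp
between samples.  Everything derives from one seed; equal seeds give
byte-identical BED files.

What the generator does **not** emulate: mappability and GC bias,
duplicate reads, fragment-length variability, overdispersion beyond
Poisson, peak-width variation, and correlated background structure.
Passing tests therefore demonstrate correctness of the algorithms and
calibration under the stated model, not performance on any real library.
In particular the Audic–Claverie null is exact for Poisson noise but
anticonservative under biological overdispersion — on real replicates the
combined |M|/P cutoff, not P alone, should be used.

## Problem sizes and numerical notes

The test suite and the acceptance script run desk-scale problems — up to
1,000 common peaks and ~500k simulated tags, P-value grids to counts of
200–400 — sizes at which every stochastic check has comfortable margins.
Degenerate inputs fail loudly: empty/inverted intervals, < 2 fit points or
constant A, |b| ≥ 2 in rescale mode, zero-length gene universes, motifs
with non-positive consensus scores.  Ties anywhere (pairing, merging,
nearest-peak) are broken by fixed deterministic rules so reruns are
byte-identical.
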