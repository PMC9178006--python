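# Methods

## Problem setting

During the mouse oocyte-to-embryo transition the repressive histone mark
H2AK119ub1 is globally erased between the germinal-vesicle (GV) and
metaphase-II (MII) oocyte stages and re-established in two-cell embryos;
oocyte-specific loss of the deubiquitinase USP16 blocks the erasure and
impairs zygotic genome activation (ZGA). Profiling this mark from a few
hundred cells relies on carrier-assisted ChIP-seq, which has two
consequences this package is built around: a high, genomically uniform
background, and no spike-in, so cross-stage comparisons must be anchored on
that background rather than on total read counts.

## Coordinate and counting conventions

All coordinates are 0-based, half-open (BED). A gene's TSS is `start` on
the '+' strand and `end - 1` on the '-' strand; promoters are TSS ± 2 kb
clipped to the chromosome. Signal tracks use sliding tiles of 1000 bp
placed every 200 bp. Reads are assigned to tiles and to promoters by their
midpoints: each read contributes to every tile covering its midpoint, and
to at most one promoter. Duplicate removal keeps one read per
(chromosome, start, end, strand). Tile values are RPKM:
`count / (binsize/1000) / (total_reads/1e6)`.

## Background-anchored normalization

For each track the background level is the 20%-per-tail trimmed mean of
RPKM over tiles whose midpoints fall inside randomly sampled regions
(default 10,000 regions of 5 kb, sampled uniformly over the genome and
allowed to overlap genes — the background should be sampled as-is). Each
track is rescaled by (reference background / own background), the first
track serving as reference; the applied factor is stored as
`background_scale`. The trimming makes the anchor robust to the minority
of random regions that land on true signal. The same per-sample background
level (as a raw tile-count mean) supplies the normalization factors for
promoter-count testing, because contrasts with near-global signal loss
violate the "most features unchanged" assumption behind median-of-ratios
size factors. The median-of-ratios estimator is implemented and exposed
for contrasts where that assumption holds.

## Broad-domain peak calling

Each tile's raw count is tested against a global Poisson rate estimated
from the random-region tiles of the same track (per-sample efficiency
cancels in the count space). Upper-tail p-values are BH-adjusted across
all tiles; tiles at q ≤ 0.05 are merged into domains when gaps are
≤ 1000 bp; merged domains carry the mean RPKM of their tiles and the
minimum q. Domains with mean RPKM < 1 or width < 800 bp are discarded.
The caller is verified tile-for-tile against a brute-force
enumerate-threshold-merge-filter oracle on hundreds of random tracks.

## Promoter differential enrichment

Promoter counts are modeled as negative binomial. Per gene, dispersion is
estimated by method of moments, `alpha = (var - mean) / mean^2`, pooled
across the two groups with degree-of-freedom weights and floored at 1e-8.
The Wald statistic is the log2 fold change of normalized group means (a
symmetric pseudo-mean of 0.5 keeps label-swap antisymmetry exact) divided
by its delta-method standard error from the NB mean-variance relation.
Because the dispersion is a plug-in estimate from few replicates, p-values
use a t reference with `n_A + n_B - 2` degrees of freedom rather than a
normal; at the study's replicate number (3 vs 3) this calibrates the null
rejection rate to ~0.034 at nominal 0.05 (Monte-Carlo, 10 × 2000 null
genes) at the cost of some power. Compared with DESeq2 (pyDESeq2) on
planted 8-fold changes the test is conservative: essentially everything it
calls, DESeq2 also calls, and it retains ≥ 75% of DESeq2's detections.
This is a deliberate divergence from DESeq2's empirical-Bayes dispersion
shrinkage, keeping the estimator self-contained and transparent. Genes
with normalized counts below 5 in every sample are not tested. Gene sets
use q < 0.05 and |log2FC| > 1 (configurable): MII-ub-down and
two-cell-ub-down from the GV→MII and GV→two-cell wild-type contrasts,
cKO-MII-ub-up from wild-type vs knockout MII.

## Expression logic

FPKM tables are floored before any fold change: genes below 1 FPKM in all
samples are dropped, remaining sub-1 values are clamped to 1 — this is
what keeps ratios of barely-expressed genes from exploding. ZGA genes are
those with floored two-cell/zygote fold change strictly above 3;
knockout-responsive transcripts use the same 3-fold rule per direction;
USP16-sensitive ZGA genes are the intersection of the ZGA set with the
knockout down-set (set algebra, not a second test). Replicates are
averaged per condition (mean; median available). The exclusion rule spans
the full table across stages and genotypes.

## Co-occupancy clustering

Features are promoter signals per mark, log2(x+1)-transformed and z-scored
per feature (heavy-tailed RPKM otherwise dominates distances). K-means
uses k-means++ with 10 restarts and keeps the lowest-inertia solution;
labels are re-ordered by descending mean of the first feature so cluster
numbering is reproducible. Gene-set association per cluster reports the
set fraction, its fold over the cluster's universe share, and BH-adjusted
hypergeometric upper-tail p-values.

## Metaplots

Profiles sample the normalized track at fixed offsets from each TSS,
flipping the axis for '-' genes so positive offsets always point
downstream of transcription; the value at a genomic position is the mean
over all sliding tiles covering it. Out-of-bounds positions are dropped
per gene with the per-offset denominator tracked. Window ±5 kb, step =
track stepsize. Matched random control sets are drawn with the same
cardinality as the target set.

## qPCR ratios

The amplification base is fixed at 2. Primer efficiency of the two gene
assays comes from plasmid standards carrying each gene fragment next to a
shared reference (Gfp): `2^-(Ct1-Ct3) / 2^-(Ct2-Ct4)`. The relative
transcript ratio normalizes sample Cts to Gapdh (which cancels
algebraically, `2^(Ct_g2-Ct_g1)`), and the absolute ratio divides the
relative ratio by the efficiency. Replicates are averaged on the Ct scale,
equivalent to a geometric mean of quantities. No standard-curve slope
fitting is performed.

## Synthetic data: what it emulates and what it does not

The generator plants: a 15 Mb three-chromosome genome with 300
non-overlapping single-TSS genes; 150 genes marked at GV with 4 kb
TSS-centered domains at 20-fold enrichment over a 70% uniform background;
90% of marked genes losing the mark at MII in wild type with full
retention in the knockout; re-establishment at the two-cell stage except
at a 30-gene subset of the MII losses; an active narrow mark (H3K4me3)
and a repressive broad mark (H3K27me3, drawn from within the ub-marked
genes) for co-occupancy; 60 ZGA genes switching on between zygote and
two-cell with a 20-gene knockout-sensitive subset; 5e5 unique reads per
sample, 50 bp, 10% exact-duplicate injection, 3 replicates drawn i.i.d.
with split seeds. Within-domain read positions follow a triangular
density peaked at the TSS, so the expected TSS profile has a unique
maximum at offset 0 (a flat-top domain convolved with 1 kb tiles would
have an argmax undefined on a plateau). The 70% background fraction and
20-fold enrichment are declared assumptions — the protocol's
signal-to-background is not quantified anywhere authoritative — chosen to
stress the background-anchored normalization while keeping single-sample
peak calling non-trivial.

Not modeled: sequence content, mappability, GC bias, fragment-length
effects, carrier-species mixtures, isoform structure, or biological
replicate variability beyond resampling noise. Passing recovery tests
therefore demonstrates the pipeline's statistical correctness under its
own model assumptions, not performance on real libraries.

## Problem sizes and determinism

Default analyses run on the 15 Mb genome (75k sliding tiles per
chromosome) with 14 samples; the full pipeline completes in well under a
minute on one core. All generators and the pipeline are pure functions of
(parameters, seed); one root seed is split per stage via
`numpy.random.SeedSequence`, and identical (config, seed) pairs produce
byte-identical tabular outputs.

## Known limitations

* One TSS per gene; alternative promoters are out of scope.
* The read-extension behavior of conventional callers is replaced by
  midpoint binning; differences are confined to sub-bin resolution.
* The NB test's moment estimator loses power relative to shrinkage
  estimators when counts are moderate (~50) and replicates few.
* Background normalization assumes the background dominates the trimmed
  region distribution; a sample whose signal covers most of the genome
  would violate the anchor.
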