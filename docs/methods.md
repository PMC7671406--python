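# Methods

This note documents what `intronseq` computes, the assumptions behind each
step, the defaults and why they were chosen, and what the synthetic-data
generators do and do not emulate.

## Coordinates and annotation flattening

All internal coordinates are 0-based half-open; GTF input and SAF output are
1-based inclusive, converted only at the I/O boundary.  A gene's *exon
parts* are the union of the exons of all its transcripts (unioned per gene,
never across genes); *intron parts* are exactly the gaps between consecutive
exon parts; the *genebody* spans the first to the last exonic base.  These
three sets partition the genebody, so every base inside an annotated gene is
either exonic or intronic.

Choices made where the input format under-determines behaviour:

* Gene type comes from the gene-level `gene_type` attribute; when missing,
  the majority `transcript_type` is used with a warning.
* A gene whose exon records span multiple chromosomes or strands is skipped
  with a warning (trans-spliced and multi-locus genes are out of scope).
* Transcripts without exon records contribute nothing — exons are never
  synthesised from transcript spans.
* `select_isolated_genes` removes any gene whose genebody overlaps another
  gene's genebody *ignoring strand*.  Unstranded coverage cannot attribute
  shared bases to either gene, so an antisense neighbour is as disqualifying
  as a sense one.

## Counting semantics

The counting unit is the **fragment**: mates of a properly paired read are
merged into one block set and counted once; skipped-region (`N`) gaps of
spliced alignments are excluded from the blocks.  A fragment is assigned to
a gene when it overlaps that gene's features by at least one base and
overlaps features of *no other* gene at that annotation level; ambiguous
fragments are discarded.  Exon and genebody counting are independent
passes, which makes the rule deliberately asymmetric: a fragment over the
exon of gene A and the intron of gene B is exon-assignable (one gene's
exons) but genebody-ambiguous (two genebodies).  Because of this, exon
counts can exceed genebody counts for some genes; intron counts are
`max(genebody − exon, 0)` and the clamp mask is reported.  Unmapped,
secondary and supplementary records are always excluded; duplicates are
kept by default (flag to drop) and the MAPQ threshold defaults to 0.
Strandedness is configurable (`none`/`fwd`/`rev`) and defaults to
unstranded.

Split-read QC: a gapped fragment whose blocks all lie within one gene's
intron parts is counted as "split in introns" (evidence of an unannotated
exon); one with any block over an exon part as "split in exons".  Per-sample
medians and third quartiles summarise annotation completeness.

## The joint differential-expression workflow

1. **Filtering.**  Each count set is filtered independently with the
   standard expression rule: keep genes whose CPM (on the median-library
   scale implied by `min_count = 10`) is reached in at least as many samples
   as the smallest group holds (damped to `10 + (n − 10)·0.7` beyond 10),
   and whose total count is ≥ 15.  Only genes kept in **both** sets are
   modelled and categorised; genes kept in one set are reported separately,
   uncategorised.
2. **Combined library sizes.**  The per-sample depth denominator is the sum
   of the filtered intron and exon counts.  Intron/exon read *proportions*
   vary between samples and protocols, so either set's own column sums are a
   poor proxy for sequencing depth; their sum is used for TMM, log-CPM,
   log-RPKM and the precision weights in both sets.  "Filtered" is the
   default reading ( `libsize="raw"` preserves the alternative).
3. **TMM.**  Scaling factors are computed per count set against the
   combined library sizes: reference sample by upper-quartile closeness to
   the mean, two-sided trimming of log-ratios (30%) and abundances (5%),
   inverse approximate binomial variance weighting, geometric mean rescaled
   to 1.  The implementation is cross-validated against edgeR's
   `calcNormFactors` in the test suite.
4. **Precision weights.**  Log-CPM with offset 0.5; per-gene unweighted
   fits give residual SDs whose square roots are lowess-smoothed (span 0.5,
   3 robustness iterations) against average log2 count; each observation's
   fitted log2 count is interpolated on the trend (constant beyond the
   range) and weighted by the inverse fourth power.  Fewer than 10 genes
   falls back to constant weights.
5. **Moderation.**  Per-gene weighted least squares; the variance prior
   (d₀, s₀²) is estimated by digamma/trigamma moment matching on
   log s_g², with the trigamma inversion done by Newton iteration (d₀ = ∞
   when the excess variance is non-positive).  Moderated t uses d₀ + d_g
   degrees of freedom.  Cross-validated against limma's `squeezeVar`.
6. **Adjustment and categories.**  BH step-up per count set (NaNs pass
   through and are excluded from n).  A gene's category combines the two
   (significant, sign) calls at adjusted p < α, default α = 0.01, with no
   logFC cutoff.  A significant test whose logFC is exactly zero is treated
   as non-significant for direction (practically unreachable).

Exploratory statistics use the conventions: offset 2 for log-CPM and
log-RPKM (lengths are total exon or total intron length per gene), offset 1
for the per-sample exon–intron log-count Pearson correlation (restricted to
genes with both counts ≥ 3), and per-library expression patterns with the
count-≥3 / ≤2 thresholds (`both`, `exon_only`, `intron_only`,
`unexpressed`, percentages among expressed genes averaged across
libraries).  MDS distances are leading-logFC distances: the root-mean-square
of the top-500 largest absolute log-CPM differences, selected per sample
pair; coordinates come from classical MDS of the double-centred squared
distance matrix, with eigenvalue fractions as variance explained.

## Coverage engine

Depth is the number of fragments with an aligned block covering a base,
stored run-length encoded per contig; all statistics are length-weighted
over runs and therefore exactly equal per-base loops (asserted to 1e-9 in
tests).  Summaries are on the log2(depth + 0.5) scale: mean, sample SD,
maximum, and the number of bases above a threshold (default log-coverage 2,
i.e. depth > 3.5) per gene × sample × region type.

*Relative log-coverage* divides per-base log-coverage by the per-gene,
per-sample, per-**region-type** maximum (a `shared_max` flag pools exon and
intron bases instead; per-region is the default because exon and intron
profiles are summarised separately).  Genes whose region maximum is ≤ 0
(depth ≤ 0.5 everywhere) are excluded from profiles — dividing by a
non-positive maximum would flip signs.  The genebody is cut into W = 20
contiguous windows (base i of an L-base gene goes to window
`⌊i·W/L⌋ + 1`, sizes differing by ≤ 1 base), ordered 5'→3' (reversed for
minus-strand genes).  Aggregation across genes uses genebody-length
tertiles (short / regular / long), averaging the per-gene window means over
genes contributing at least one base of the region type to the window.

### IR screening

A gene is IR-like when, jointly:

* mean exon log-coverage > 2 (the gene is well expressed in exons),
* SD of intron log-coverage > 1.5 (one intron stands out against quiet
  neighbours — uniform pre-mRNA coverage has low SD), and
* at least 150 intron bases above log-coverage 2 (default
  `bases_above_min`) — a stretch comfortably longer than a typical exon
  (~150 bp), so single misannotated exons or edge effects do not qualify.

With `data_driven=True` the first two cutoffs become the across-gene means
of the respective statistics and the third becomes the 99th percentile of
the bases-above distribution; that mode suits genome-scale gene sets, where
"top 1% of genes" is a meaningful tail, while the fixed-count default
behaves sensibly on small gene panels too.  Multi-sample summaries are
combined by requiring a gene to pass in all samples (default), any sample,
or on across-sample mean statistics.  Selection is monotone in all three
thresholds.  The method is a screen, not a test: it ranks and flags
coverage shapes and performs no statistical inference on profiles;
condition comparisons are done by running it per condition and comparing
gene lists.

## Synthetic data

`make_toy_annotation` lays multi-exon genes (defaults: 3–8 exons of
100–300 bp, introns 200–3000 bp) left to right on one contig; genes with
≥ 3 exons get a second transcript missing one internal exon so flattening
performs real unions.  `simulate_fragments` draws, per gene, a binomial
split between mature fragments (sampled on transcript coordinates, emitted
as spliced alignments) and pre-mRNA fragments (unspliced, sampled along the
genebody).  Under `polyA`, fragment starts are drawn with density
∝ exp(b·t/L) toward the 3' end (default b = 3, giving an ≈ e³ ≈ 20-fold
5'→3' weight ratio — enough to reproduce the qualitative 3' rise of poly(A)
intron coverage); under `totalRNA` they are uniform.  Pre-mRNA molecules
are fully unspliced; retention events add contiguous reads within one
designated intron at a depth tied to the gene's exon depth.  The default
`premrna_fraction` of 0.2 sits in the range implied by observed intron-read
proportions in total-RNA libraries.  Reads are 75 bp, single-end by
default (paired mode emits proper pairs merged back to one fragment by the
counter); base qualities, sequencing errors, duplicates and GC bias are not
modelled.  `simulate_counts` draws negative-binomial counts (variance
m + φm², default φ = 0.05) with log-normal baseline exon means (median 150)
and intron means a configurable ratio of them (default 0.3), applying
group-2 fold changes independently to exon and intron counts and recording
each gene's implied category as truth.

Because the generators contain none of the machinery they are used to test
(reads are written as SAM text and re-parsed; truth tallies are brute-force
block-overlap counts), agreement between pipeline output and generator
truth is a real end-to-end check.  What passing these tests does **not**
show: robustness to misannotation, soft-clipping, multimapping, partial
splicing intermediates, or fragment-length artefacts of real libraries.

## Problem sizes and numerical choices

The validation studies (test suite and `scripts/acceptance.py`) use: 20
random fixtures of ≤ 50 genes / ≤ 600 fragments for exact counting
agreement; 10 complete-null simulations of 2000 genes (3 vs 3, φ = 0.05)
for calibration — well under 5% of genes leave category "0", in practice
essentially none; one 2000-gene simulation with 100 planted intron-only
4-fold changes for sensitivity (≥ 80% required, ~96% observed); nine-gene,
~12 000-fragment coverage simulations per protocol for the profile
regimes; and a 100-gene screen with 5 planted retained introns for IR
recovery.  These sizes keep the full suite to a few seconds per study
while leaving wide margins to the asserted bounds.

Tolerances: BH agrees with its step-up transcription to 1e-10, TMM to
1e-6, the variance prior to 1e-4, coverage statistics to 1e-9 (exact
arithmetic on runs).  Ties in the window map are resolved by the explicit
floor rule above; TMM trimming uses average ranks; the trigamma inversion
iterates Newton steps to a relative 1e-8.

## Known limitations

* GFF3 is not read; only the GENCODE GTF attribute dialect is supported.
* No transcript-level or isoform-aware quantification; the unit is the
  flattened gene.
* The DE workflow supports a single contrast vector over a full-rank
  design; no blocking, duplicate correlation or quasi-likelihood tests.
* IR screening is per-condition and descriptive; differential retention is
  left to list comparison between conditions.
* Coverage is unstranded; the isolated-gene preselection is the intended
  guard against ambiguity from overlapping genes.
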