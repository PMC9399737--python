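# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open (BED convention). GTF I/O
converts at the boundary (GTF is 1-based, closed). A read is reduced to its
5′ end and strand: for `+` reads the stored position is the 5′-most covered
base; for `-` reads it is the exclusive coordinate of the 5′ terminus (BED
`end` style), so a `-` read at position p extended to `ext` bp covers
`[p − ext, p)`.

## Coverage model and normalization

Reads are extended to `ext` bp (default 150, matching typical sonicated
ChIP fragments sequenced as 50 bp single-end reads) from their 5′ end in the
strand direction, clipped at chromosome bounds. Tracks are per-chromosome
stepwise functions stored run-length encoded; bedGraph is the canonical
on-disk form and round-trips bit-exactly (values are written with shortest
round-trip precision and parsed with pandas' round-trip parser).

Normalization multiplies pileup depth by `1e6 / n`, where `n` is the read
count aligned to the primary genome (RPM) or to the exogenous spike-in
genome. The scaling is computed as `(depth / n) * 1e6` rather than
`depth * (1e6 / n)`: the former is bit-exactly invariant under integer
c-fold duplication of reads and counts (`(c·d)/(c·n)` rounds identically to
`d/n`), which is the defining property of spike-in normalization and is
asserted exactly in the tests.

Ratio tracks (e.g. a target mark over an H3 control) are computed run-wise as
`(num + eps) / (den + eps)`. The pseudocount `eps` (default 0.5) bounds the
ratio in zero-coverage regions and forces 0/0 → 1; the published procedure
does not state a zero-handling rule, so the default is a package choice and
is configurable.

## Gene selection filters

Two selections feed the downstream statistics:

* **Metagene genes** — protein-coding genes with annotated span ≥ 600 bp
  (span length, i.e. TES − TSS, not summed exon length — the metagene body
  binning operates on the span) whose ±2 kb window, clipped at chromosome
  bounds, intersects no other annotated gene span of any biotype on either
  strand. The neighbor test deliberately includes non-coding genes: the
  isolation requirement is about contaminating signal, which any transcribed
  neighbor produces.
* **Enrichment transcripts** — the longest transcript (span length; ties
  break to the lexicographically smallest id, for determinism) of each
  protein-coding gene; then every transcript whose span overlaps any other
  selected transcript's span, strand ignored, is removed. Both members of an
  overlapping pair are dropped — symmetric removal is order-free, where a
  keep-one rule would depend on iteration order.

Both filters are implemented with sorted sweeps that are proven equivalent to
the all-pairs definition in the test suite (a transcript overlaps an earlier
one iff the running maximum of earlier ends exceeds its start; a later one
iff the next start precedes its end).

## Metagene binning

Each selected gene contributes 500 bins: 100 fixed 20 bp bins upstream of the
TSS, 300 body bins, 100 fixed bins downstream of the TES. Body bin k spans
`[round(k·L/300), round((k+1)·L/300))` relative to the gene start
(round-half-up on exact halves); widths therefore differ by at most 1 bp and
are ≥ 2 bp for any gene passing the 600 bp filter. For minus-strand genes the
bin list is reversed so index 0 is always biologically upstream. Flank bins
that run off the chromosome contribute clipped means; a bin left entirely
off-chromosome is excluded from that bin's average (per-bin contributing-gene
counts are kept alongside the profile). Genes are equally weighted — the
profile is a mean of per-gene bin means, the standard metagene convention —
rather than read-weighted.

`body_skew` is `log2((m5 + eps) / (m3 + eps))` with `m5`/`m3` the means of
body bins 1–150 and 151–300; positive values mean 5′-heavy profiles. `eps` is
shared with the ratio-track pseudocount.

## Exon/intron enrichment

Introns are the non-empty gaps between consecutive exons of a transcript
(abutting exons produce no intron), so exons and introns tile the transcript
span disjointly and every base contributes to exactly one category. The
pooled estimator divides total exon signal by total exon length (likewise
introns) across the whole transcript set; the per-transcript score is the
ratio of that transcript's exon and intron means. Per-transcript scores are
*undefined* — not zero, not pseudocounted — for single-exon transcripts and
for transcripts with zero intron signal; undefined scores are counted, logged
and excluded from aggregates. An eps-based variant was considered and
rejected: the published score is a plain ratio, and a pseudocount would bias
exactly the sparse transcripts the undefined policy flags.

## Peak feature annotation

Categories are Intergenic, 5UTR, 3UTR, Exon (exonic bp not annotated as UTR;
UTR categories are populated only from explicit `five_prime_utr` /
`three_prime_utr` features), Intron (derived), and Intergenic (complement of
gene spans). A peak takes the first category in the priority order it
overlaps by ≥ 1 bp — there is no minimum-overlap-fraction rule. The default
priority lists Intergenic first and is applied literally: a peak with any
intergenic overlap is called Intergenic. This mirrors the annotator options
the analysis specifies, but note that common annotators may internally
re-rank categories; the priority is a parameter precisely because this
behavior is unusual. Promoter is not a category because the priority list
omits it.

`peak_overlap_fraction(a, b)` is the fraction of peaks in `a` with ≥ 1 bp
overlap of any peak in `b` — asymmetric by definition.

## Expression linkage

Strata use the published TPM cutoffs (coding: low 0 < TPM ≤ 2, high TPM ≥ 4;
lncRNA: low 0 < TPM ≤ 0.1, high TPM ≥ 0.5); TPM = 0 and gap genes belong to
neither stratum, so low and high are disjoint by construction. "Fold change
≥ 2" is interpreted as |log2FC| ≥ 1, boundary-inclusive, matching the printed
"≥"; FDR ≤ 0.05 likewise inclusive. Splicing events are filtered on FDR only,
and a gene enters the Up (Down) set if it has at least one significant
positive (negative) delta-PSI event — a gene with both kinds appears in both
sets. Gene-level signal for stratum boxplots is the mean over the annotated
gene span (not peak-based — a peak-free definition is robust to peak-caller
choices). Quartiles use linear interpolation between order statistics (the
common plotting default; the convention is switchable through the numpy
quantile `method` parameter), whiskers are the most extreme data points
within Q1 − 1.5·IQR and Q3 + 1.5·IQR, and points beyond are reported as
outliers.

## Synthetic data: what it emulates and what it does not

The generator builds non-overlapping genes with alternating strands on
fixed-length chromosomes; exon counts 1–8, exon lengths 300–1500 bp, intron
lengths 1000–4000 bp, and a configurable fraction (default 0.15) of
inter-gene gaps drawn below the 2 kb isolation flank so the metagene filter
has known violations to find. Ground truth records, per gene, the biotype,
structure, longest transcript, and whether it is crowded or too short — so
the selection filters can be tested for exact set recovery rather than
plausibility.

Within a gene the expected extended-fragment coverage is

    lambda(x) = base_depth · tpm^expr_coupling · (rho if x exonic else 1)
                · (1 + gamma · (pos(x)/L − 0.5))

with `pos` measured 5′→3′, a flat intergenic background of
`0.05 · base_depth`, and defaults `rho = 3`, `gamma = 0`, `base_depth = 30`,
`expr_coupling = 0` (expression coupling is opt-in so the rho/gamma recovery
targets stay exact). `gamma > 0` is 3′-heavy — the canonical skew of
co-transcriptional marks — so `body_skew` decreases monotonically in gamma.

Noise modes:

* `none` — the returned track *is* lambda, so per-transcript enrichment
  equals rho exactly and skew is exactly 0 at gamma = 0.
* `poisson` — 150 bp fragment midpoints are drawn per base at rate
  `lambda/ext` and emitted as 5′-anchored reads (strand labels Bernoulli(½);
  both strands reconstruct the same fragment). The expected pileup is then an
  ext-wide moving average of lambda.

The moving average matters: it smears exon/intron boundaries over ±75 bp,
which biases region means toward each other and the exon:intron score toward
1\. With this generator's geometry the bias leaves the median per-transcript
score ≈ 2.8 for a true rho of 3 (≈ 6%); with real human exon lengths (median
≈ 140 bp) the same smearing would push the score near 2.5. The synthetic
exons are therefore deliberately *longer* than real ones — a green recovery
test establishes that the estimator is correct on signal dominated by region
interiors, not that fragment-scale smearing is negligible on real data.
Other simplifications: no sequence content, mappability or GC structure; no
duplicate reads; non-overlapping genes only; spike-in reads are represented
by their count alone (only the count enters the normalization formula).

Splicing-event tables are written in the rMATS column layout
(`GeneID`, `IncLevelDifference`, `FDR` are the consumed columns), cycling
event types through SE/A5SS/A3SS/MXE/RI, with significant events drawn at
FDR < 0.05 and nonsignificant ones at FDR ≥ 0.1 — safely away from the 0.05
boundary, which is exercised by dedicated boundary tests instead. TPMs are
log-normal (lncRNA scaled down 20×); if a biotype's low or high stratum would
come up empty, the most extreme draw is nudged inside it, so stratum tests
are never vacuous.

All generators are deterministic functions of their integer seeds
(numpy `default_rng`; coordinates use integer arithmetic).

## Numerical choices

* Track equality used in tests is exact run-by-run equality of the canonical
  (merged) run-length form.
* Pooled/per-transcript means are computed from run-length integrals via
  prefix sums (`O(log runs)` per query), validated against a naive per-base
  loop to 1e-9 relative.
* `round(i·L/300)` uses floor(x + 0.5) — deterministic half-up — so bin
  edges are platform-independent.
* Degenerate inputs fail loudly: empty gene/transcript/peak lists, zero
  alignment counts, zero total intron length, overlapping bedGraph intervals,
  reads off-chromosome, genes shorter than the binning minimum.

## Known limitations

* bigWig I/O is not provided (no bigWig library in the supported
  environment); bedGraph is the interchange format.
* The feature index has no Promoter category and no nearest-gene annotation.
* Peak calling, alignment, differential expression and differential splicing
  are upstream tools; only their tabular/BED outputs are consumed.
* Dataset-scale published figures (peak counts, 92% peak overlap, DE/AS
  event counts, the ≈1.5 enrichment in real chromatin) depend on the real
  sequencing data and annotation release and are out of the package's scope;
  the tests verify structural exactness and parameter recovery on the
  synthetic world instead.
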