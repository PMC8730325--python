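# Methods

## Scope and model

pirnakit characterises piRNA populations in 18–30 nt small-RNA libraries
by their sequence signatures: length (~27 nt vs ~22 nt miRNAs), 5′-uridine
bias, antisense orientation toward transposons, resistance of
2′-O-methylated 3′ termini to periodate oxidation, a 5′UTR-biased metagene
profile of genic piRNAs, and the ping-pong amplification signature. The
pipeline assumes a reference genome and strand-aware annotations (genes
with 5′UTR/CDS/3′UTR sub-features, transposon copies with family labels,
miRNA and structural ncRNA loci) are given; it does not predict genes or
discover repeats, and it does not call piRNA clusters.

## Coordinates and annotation

All coordinates are 0-based half-open internally; GFF3 (1-based closed)
and BED6 conventions are converted only at the I/O boundary. Transposon
families are free-form two-level labels ("superfamily/family", e.g.
`LTR/Gypsy`) split on `/`; no deeper repeat taxonomy is imposed. Unknown
feature types are folded into `other_ncRNA` with a warning, which also
makes the structural-ncRNA exclusion list extensible through the
annotation itself. Medians of region lengths use the mean-of-middle rule
for even counts; when an annotation supplies no usable gene models the
documented defaults 350/1000/800 nt are used.

## Mapping and apportionment

Reads are collapsed to unique sequences with counts and placed at every
locus where they match the genome exactly, on either strand, via a hashed
seed index (default seed length 18 nt, the minimum read length) with
full-length verification. Mismatched reads are simply unmapped: with
perfect matching there is no scoring ambiguity, and reporting *all*
placements is the only mode consistent with uniform apportionment. A
multi-mapping read's count is split as count/n over its n placements, so
placement weight is conserved exactly per read. An optional `max_hits` cap
(off by default) discards promiscuous reads in the style of aligner hit
limits. SAM/BAM import accepts only ungapped, full-length, NM=0 records;
everything else is skipped with a logged count.

## Classification and normalisation

A placement is attributed to a feature when ≥50% of the read lies inside
it (configurable); a read's class is the highest-priority class over its
placements, with priority structural ncRNA > miRNA > transposon > genic >
unannotated (a permutation can be supplied). Transposon outranks genic
because transposon-derived reads inside genes (e.g. intronic copies) are
counted as transposon reads. piRNA candidates are reads ≥24 nt (the >23 nt
size partition; ≥23 is available via `min_pirna_len`) outside the
miRNA/ncRNA classes. Abundances are ppm of mapped weight minus structural
ncRNA weight, so the four remaining classes sum to 10⁶ exactly.

## Ping-pong signature

5′ ends are the placement start (+) or end−1 (−). The overlap histogram
multiplies apportioned 5′-end weights of opposite-strand position pairs at
distances 1–20 (product weighting; a `min` mode is provided since the
literature is not uniform on pair weighting). The Z-score uses distances
{1–9, 11–19} as background with the sample SD (divisor 17); d=20 is
tabulated but excluded from the background. A zero-variance background
yields an invalid (NaN) score rather than an exception. Per-family scores
restrict the 5′-end map to placements majority-overlapping that family's
copies; cross-family pairs therefore count only toward the overall score.
Significance is one-sided normal at α=0.05 (z ≥ 1.645), configurable.

## Metagene profile

Genic piRNAs are represented by their 5′ end (a piRNA's identity is
defined by its 5′ end; a full-coverage assignment mode was considered and
deliberately omitted to keep one well-tested assignment path). The 5′ end
is located in transcript coordinates; intronic 5′ ends are excluded from
the profile and tallied separately. A read at offset x in a region of
length L falls in scaled bin ⌊x/L·B⌋ (clamped), with B = 350/1000/800 for
5′UTR/CDS/3′UTR. Bin weights are converted per gene to an RPKM-like
density (weight per kb of the bin's genomic extent per million mapped
reads) and averaged across genes with equal weights, so long or highly
expressed genes do not dominate; only genes with all three regions present
enter the profile. Enrichment between regions is tested on per-gene region
RPKM with the Wilcoxon rank-sum test: exact two-sided p by enumeration of
all C(n, n_x) group assignments (midrank ties) for combined n ≤ 12, and
the tie- and continuity-corrected normal approximation above that. The
top-quartile gene selection ranks by total genic piRNA weight, ties broken
lexicographically, taking ⌈n/4⌉ genes.

Because the 2,150 raw bins are individually noisy at realistic depths,
"flatness" of a profile is judged on the three region means rather than on
single-bin extremes.

## Expression

Counts per gene and per transposon family (copies pooled; family length =
summed copy lengths) use the same ≥50% overlap rule, with transposons
taking precedence so each placement is counted once and total mapped
weight is conserved across features plus the unannotated remainder. RPKM
uses the library's mapped weight. Fold changes are log2 ratios of
per-million-scaled counts with a pseudocount of 1; |log2FC| > 1 rows are
flagged. Dispersion modelling and significance calling for differential
expression are intentionally left to dedicated DE tools, which can consume
the exported count matrix directly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
configurable scale, with a single seeded RNG (fixed seed ⇒ byte-identical
outputs):

- **Genome** — i.i.d. uniform background; per family, a random consensus
  (600–1,500 nt) copied 20× with 2% per-copy substitutions and inserted at
  non-overlapping positions on random strands. The 2% rate keeps copies
  multi-mapping for 24–30 nt reads while remaining distinguishable, which
  exercises the apportionment path. Genes (contiguous 5′UTR/CDS/3′UTR,
  log-normal lengths with medians 350/1000/800 nt), miRNA loci (lengths
  ~N(22, 0.8) clipped to 20–23) and rRNA loci fill transposon-free space;
  large features are placed first so the free space does not fragment
  before they fit.
- **Reads** — transposon piRNAs (~N(27, 1.5) nt clipped to 24–30) are
  drawn antisense to their copy with probability 0.8; genic piRNAs (55% of
  piRNAs) are sense reads with per-nt region weights 8:1:1 over
  5′UTR:CDS:3′UTR. The 5′ base is uridine with probability exactly 0.85,
  realised by rejection-sampling start positions whose genomic 5′ base is
  T — reads are never edited, so every read re-maps perfectly to its
  origin. A fraction f=0.3 of transposon primaries receives a secondary
  partner on the opposite strand with an exact 10-nt 5′–5′ overlap at the
  same locus (cut-site model), making c₁₀ directly interpretable from
  truth counts. Because a secondary's 10th base is the complement of its
  primary's first base, the planted 10-A frequency of secondaries (0.7) is
  realised by tilting which primaries receive partners. miRNA reads copy
  their locus exactly; degradation fragments (18–30 nt) are uniform over
  gene spans; only piRNA-class reads carry the 2′-O-methyl flag.
- **Oxidation** — unmethylated reads are dropped independently with
  probability 0.99; methylated reads always survive.
- An optional per-read substitution rate (default 0) plants unmappable
  reads for the mapped-fraction path; sequencing error is otherwise off
  because the perfect-match mapper would silently discard erroneous reads.

What the generator does *not* emulate: realistic base composition,
adapter chimeras, PCR duplication, spliced genes (simulated genes are
intronless; intron handling is exercised by hand-built gene models in the
tests), and multi-contig fragmented assemblies. Passing tests therefore
demonstrate correctness of the measurement machinery under the planted
statistical structure, not robustness to every artefact of real libraries.

### Consequences of the cut-site construction

Secondary reads inherit their 5′ base from the genome opposite the
primary's 10th position and sit on the opposite strand of their (mostly
antisense) primaries. The pooled piRNA population therefore has, by
construction, a lower 1U fraction than 0.85 and a lower antisense fraction
than 0.8. Recovery of the planted parameters is accordingly measured on
the population each parameter describes — 1U on primary/genic reads, 10A
on secondaries, antisense bias on transposon primaries — using the truth
table to select reads and the ordinary analysis code to measure them.

## Problem sizes

The test suite runs the simulator at reduced scale (genome 120–200 kb,
2–4 families × 6–10 copies, 8–25 genes, 0.8–12 k piRNAs) with every
statistical parameter at its default; the acceptance script runs the full
default conditions (500 kb, 6 × 20 copies, 60 genes, 50 k piRNAs, 20 k
miRNAs, 5 k degradation reads). Null calibration of the Z-score uses 100
libraries of 4,000 uniformly random 5′ ends on a 20 kb span. Statistical
recovery checks use two-binomial-SE tolerances at the realised sample
sizes.

## Known limitations

- Perfect-match mapping discards any read with a sequencing error; real
  libraries should be quality-filtered first, and the observed mapped
  fraction conflates error rate with genome completeness.
- Per-family Z-scores share reads between overlapping family annotations.
- The metagene profile ignores splice structure beyond excluding intronic
  5′ ends.
- ppm normalisation depends on the completeness of the structural-ncRNA
  annotation; missing rRNA loci inflate all ppm values.
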