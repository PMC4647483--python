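# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter when
reading results.

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)`. GTF I/O
converts to and from 1-based inclusive at the file boundary; BED6 is
native. Strand is stored on every object but `overlap_length` is
deliberately strand-blind: each classifier states its own strand policy,
because the analyses differ (co-expression pairing is same-strand by
default; read-location assignment is strand-blind by default since the
counting rule for the stranded libraries is not fixed by the study
design, and is exposed as `strand_aware=`). UTR intervals are always
derived as exonic-minus-CDS rather than parsed, which keeps the model
robust across GTF dialects.

## Expression census

RPKM is computed from its definition,
`rpkm(g,s) = 1e9 · counts(g,s) / (exonic_length(g) · library_size(s))`,
where `exonic_length` is the length of the union of all exons across a
gene's transcripts and `library_size` is total mapped reads (not the
column sum — reads outside genes still count). A gene is *expressed* at
an inclusive threshold (default 0.5 RPKM), in at least one sample
(`any`, used for per-cell-type expressed counts) or in all samples
(`all`, the stricter census). Inclusivity at the boundary matters and
is tested.

Read-location assignment uses a fixed precedence, so every read gets
exactly one label:

1. **exonic** — ≥ 50 % of the read's bases fall in the exon union of a
   single gene. The majority rule avoids double counting at splice
   junctions; the threshold is a package decision, stated because the
   assignment rule is otherwise underdetermined.
2. **intronic** — any gene-body overlap that is not exonic.
3. **proximal_intergenic** — outside all gene bodies but within a
   window (default 10 kb) upstream of a TSS or downstream of a TES,
   strand-aware per gene.
4. **distal_intergenic** — everything else.

For a three-way exonic/intronic/intergenic report the proximal category
is ambiguous; `LocationDistribution.three_category` merges it into the
gene-associated (intronic) tally by default, with the alternative merge
into intergenic available — both readings are supported rather than
asserting one.

Top-N ranking is descending by mean with ties broken by gene identifier
ascending, making the order a pure function of the input. The packaged
table of the 25 most abundant erythrocyte long RNAs stores the published
"average relative expression" values verbatim; their normalisation is
not RPKM-calibrated, so they are treated as opaque ranking values.

## GSEA

The statistic is the weighted KS running sum: hits increment by
`|metric|^p` normalised over the gene set, misses decrement by
`1/(N−|S|)`; the enrichment score is the signed extremum. `p = 1` is
the default, `p = 0` gives the classic unweighted statistic (invariant
under monotone metric transforms; reversal of the list negates it).
The ranking metric is `log2((mean RPKM_a + c)/(mean RPKM_b + c))` with
pseudocount `c = 0.5` to keep absent genes finite — a default the study
design leaves open.

Significance uses gene-label permutation: with 2–3 samples per
phenotype, phenotype permutation is impossible. The p-value is add-one
and sign-conditioned, `p = (1 + #{same-sign |ES*| ≥ |ES|}) / (1 +
#same-sign)`, so it can never be zero and its floor is `1/(1 +
n_same_sign)` (exposed on the result); NES divides ES by the mean
same-sign null magnitude. If no permutation shares the observed sign,
the p-value is 1 and NES falls back to the all-permutation magnitude.
If every hit weight is zero (an all-zero metric with `p ≥ 1`), hit
steps fall back to equal weights rather than dividing by zero. The null
is calibrated: on random gene sets the p-values are approximately
uniform (checked by KS test in the acceptance suite).

## miRNA catalog

Candidates are consumed as miRDeep-style records; the hairpin-scoring
model itself is out of scope. Retention requires score ≥ 1 **and**
maximum single-sample mature reads ≥ 20, both inclusive — "at least one
sample" is read as a per-sample maximum, with a pooled-sum mode behind a
flag for sensitivity analysis only. Known status is an exact mature
sequence match anywhere (reference sets match by sequence) or a
same-strand hairpin overlap; everything else is putative. Genomic
location extends the coding-wins rule to a full precedence (coding >
UTR > lncRNA > intronic > intergenic); only the top of that order is
externally fixed, the rest is a documented package decision.
Abundance summaries normalise each sample by its total *known* mature
reads; the log-scale display used in figures is presentation only — the
module emits linear percentages.

## Conservation

The seed is always nucleotides 2–8 of the mature sequence, regardless
of arm or length. A species is conserved when some ungapped,
forward-orientation window of its orthologous region has zero seed
mismatches and at most one mismatch elsewhere; T and U are unified
before comparison. No gaps and no reverse complement: inputs are
orthologous regions already on the miRNA strand, and the matching rule
is exact alignment with bounded mismatches. The best window is the one
with fewest mismatches, leftmost on ties. Region acquisition (genome
alignments, liftover) is explicitly external; the synthetic generator
fabricates regions with planted mismatch positions instead.

## Co-expression loci

A transcript/hairpin pair needs ≥ 1 base of overlap, same-strand by
default. Span patterns: FULL_SPAN requires the transcript to cover the
hairpin extended by a flank (default 10 nt — the qualitative "including
flanking regions" gives no width, so the default is small and
configurable) on both genomic sides; FIVE_PRIME_ONLY requires ≥ 1 base
of the strand-aware 5p arm and 0 bases of the 3p arm (so on the minus
strand the 5' portion sits at the larger genomic coordinates); anything
else is PARTIAL_OTHER, excluded from reports unless requested. A locus
is reported only when a filter-retained mature miRNA lies inside the
hairpin on the same strand and the transcript's aggregated support
strictly exceeds the coverage floor (default 50; the strictness of
"> 50" is preserved). Whether coverage means per-sample mean, minimum,
or pooled sum is not externally fixed; all three are supported, mean is
the default. The locus report lists, per call, the transcript and every
hairpin within a 10 kb neighbourhood, so clustered arrangements (three
hairpins within 6 kb, as in the miR-144/451 cluster) appear as one
multi-element locus.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of the study inputs:

- **Genome** — ~200 non-overlapping genes (70 % coding, 20 % lncRNA,
  10 % other ncRNA) with 2–6 exons of 100–400 nt, introns 0.2–2 kb, and
  wide (25–40 kb) intergenic gaps so distal space beyond the 10 kb
  proximal windows always exists. Pre-miRNA hairpins (22 nt arms,
  14–30 nt loops) are placed intronically or intergenically per config,
  plus a 3-hairpin cluster inside a 6 kb window on one strand.
- **Reads** — single placed 50 nt intervals, not paired FASTQ: the
  analyses operate on mapped placements, so fragment pairing, sequencing
  errors and quality scores are not modelled. Each read draws its
  compartment from the configured multinomial (default 0.93 / 0.04 /
  0.02 / 0.01, the strongly exonic erythrocyte-like profile) and its
  truth label is the placement origin even if it overhangs a boundary.
- **Expression** — expressed genes (50 % of genes) draw log-normal
  relative abundances (μ = 3, σ = 1; arbitrary but separable defaults —
  no distributional parameters are externally given); unexpressed genes
  receive Poisson background at one tenth of the count equivalent of
  RPKM 0.5, which at 10,000 reads/sample is ~7.5e-4 reads per gene and
  makes the census decision cleanly separable. Recall/precision ≥ 0.95
  on this design therefore demonstrates correctness of the calling
  logic, not robustness to borderline expression.
- **Candidates** — known candidates copy a reference locus and
  sequence; putative ones get novel sequences at unannotated loci.
  Scores are log-normal clipped to ≥ 1 for planted passes, with
  deliberate failures planted below each threshold; mature read counts
  are negative binomial (dispersion 2, mean 200).
- **Ortholog sets** — each species region embeds the mature sequence,
  mutated at specified 1-based positions, inside 30 nt random flanks. A
  random flank can in principle create a spurious qualifying window;
  at 18–24 nt query lengths the probability is negligible and the fixed
  seeds used in tests avoid it.
- **Co-expression** — one transcript per planted spec with constant
  per-sample coverage, including a decoy at exactly the coverage floor
  and a decoy whose miRNA fails retention.

Hairpin secondary structure (RNAfold-style folding) is not simulated,
and the generator plants no alignment noise; passing recovery tests
shows the analysis logic is exact on clean inputs, not that it is
robust to mapping artifacts.

Determinism: every generator derives its stream from `(seed, stage)`,
so any single output is byte-identical under a fixed seed regardless of
which other generators ran; the pipeline manifest hashes make this
checkable end-to-end.

## Problem sizes and numerical choices

The test and acceptance runs use 200 genes, 3 samples × 10,000 reads,
60 filter-grid candidates, 254 exhaustive mutation placements for the
conservation rule, and 1,000 random instances per brute-force oracle
comparison; GSEA calibration uses 50 replicates × 200 permutations on a
100-gene list. These sizes were chosen so every check runs in seconds
while keeping binomial tolerances (± 0.02 on compartment fractions)
meaningful.

Fraction tables sum to 1 within 1e-9; tie-breaks (ranking by gene id,
leftmost best window, first extremum of the running sum) are all
deterministic. One genuine numerical ambiguity exists: when the running
sum's maximum and minimum tie in magnitude to machine precision, the
sign of the ES depends on float rounding; the oracle comparisons treat
equal-magnitude sign flips as agreement.

## Known limitations

- The headline cohort numbers from real erythrocyte sequencing (e.g.
  thousands of expressed transcripts, hundreds of catalogued miRNAs)
  depend on the original sequencing data and annotation/reference
  versions and are not reproduced here; the package reproduces the
  *procedures* and verifies them against planted truth and the
  published top-25 table.
- Manual curation steps in miRNA annotation are not algorithmic and are
  not modelled; only the stated automatic rules are implemented.
- The conservation caller assumes ortholog regions are given on the
  correct strand; it performs no alignment extraction.
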