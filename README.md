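# rbctx

Joint analysis of the long (>200 nt) and short (18–24 nt) RNA
transcriptomes of human erythrocytes, as a tested, reusable Python
library with a synthetic-data generator standing in for sequencing data.

Mature erythrocytes are anucleate and transcribe nothing, yet they
retain a diverse repertoire of RNAs inherited from nucleated erythroid
precursors. Characterising that repertoire means answering a chain of
questions, each of which is one module here:

- **Which transcripts count as expressed?** RPKM normalisation
  (`rpkm(g,s) = 10^9 · c(g,s) / (L_g · N_s)` for exonic length `L_g` and
  library size `N_s`) with an inclusive ≥ 0.5 threshold, in at least one
  or in all samples (`rbctx.census`).
- **Where do the reads land?** Each read is assigned one compartment
  with precedence exonic > intronic > proximal-intergenic (within 10 kb
  of a TSS/TES, strand-aware) > distal-intergenic; exonic needs ≥ 50 %
  of read bases in one gene's exon union (`rbctx.census`).
- **Is the erythrocyte signature enriched in erythroid progenitors?**
  GSEA: the weighted Kolmogorov–Smirnov running sum over a
  log2-fold-change-ranked list, with a gene-label permutation null and
  an add-one p-value estimator (`rbctx.gsea`).
- **Which short-RNA candidates are real miRNAs, and are they known?**
  miRDeep-style records retained at score ≥ 1 and ≥ 20 reads in at least
  one sample; known iff the mature sequence matches a reference exactly
  or the hairpin overlaps a reference hairpin on the same strand;
  genomic location by precedence coding > UTR > lncRNA > intronic >
  intergenic (`rbctx.mirna_catalog`).
- **How conserved are they?** A mature miRNA is conserved in a species
  when an ungapped window of its orthologous region has zero mismatches
  in the seed (nucleotides 2–8) and at most one mismatch elsewhere,
  over the panel {human, chimp, rhesus, dog, mouse, zebrafish}
  (`rbctx.conservation`).
- **Where do long and short RNAs co-occur?** Loci where an expressed
  long RNA spans a pre-miRNA hairpin, either entirely with flanks
  (FULL_SPAN) or only its strand-aware 5' portion (FIVE_PRIME_ONLY, the
  miR-4732-like geometry), reported when a retained miRNA maps inside
  the hairpin and transcript coverage strictly exceeds 50 reads
  (`rbctx.joint_locus`).

`rbctx.synthetic_data` generates all inputs — annotated toy genomes,
read placements, candidate records, ortholog sets, planted co-expression
loci — with known truth, deterministically under a fixed seed.
`rbctx.pipeline` chains everything from one YAML config and emits a
sha256 manifest of every artifact.

## Worked example

```sh
python examples/01_expression_census.py
```

```
genes: 200, planted expressed: 92
expressed in >=1 sample: 93
expressed in all samples: 91

top 5 by mean RPKM (rank, gene, value):
  1  G0140  212313.1
  ...

mean compartment fractions (planted 0.93/0.04/0.02/0.01):
exonic                 0.9311
intronic               0.0394
proximal_intergenic    0.0193
distal_intergenic      0.0102
```

The census brackets the planted truth (92 genes were simulated as
expressed; 93 clear the RPKM ≥ 0.5 bar in at least one sample, 91 in
all three), and the read-location breakdown recovers the planted
compartment fractions — the strongly exonic profile characteristic of a
mature-erythrocyte library — to well within sampling noise. The other
scripts in `examples/` walk through GSEA, the miRNA catalog,
conservation calls, co-expression locus detection, and the full
pipeline, each printing the numbers it computes and what they mean.

A command-line entry point mirrors the library:

```sh
rbctx run --out demo_run --seed 42        # simulate + analyze + manifest
rbctx census --counts ... --lengths ... --library-sizes ...
```

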