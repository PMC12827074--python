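# lilrseq

Allele discovery, alternative-splicing annotation, and lineage nomenclature
for *LILRB1*/*LILRB2* long-read amplicon sequencing in Old World monkeys.

The inhibitory leukocyte immunoglobulin-like receptors LILRB1 and LILRB2
carry four extracellular Ig-like domains (D1–D4, exons 5–8), a stem region
(exons 9–10), a transmembrane segment (exon 11), and an ITIM-bearing
cytoplasmic tail (exons 12–16). Characterizing their allelic repertoire from
barcoded PacBio circular-consensus (CCS) amplicons is complicated by two
features of the data: the genes are highly polymorphic with lineage-level
structure, and most transcripts are alternatively spliced — exon-15
skipping, alternative 3′-splice sites inserting 3 bp at exons 10/15, partial
intron retention, and frameshifting 1–2 bp micro-insertions all occur at
high frequency. `lilrseq` implements the full computational workflow as a
tested library:

- **read_processing** — read-quality filtering (rq ≥ 0.99) and dual 16-bp
  barcode demultiplexing with orientation normalization;
- **allele_discovery** — exact-match read assignment (zero mismatches over
  ≥ 400 bp, ≤ 1 ambiguous base), contig clustering of unassigned reads
  (cutoff: three reads per contig), confirmation of novel alleles in two
  independent runs or two individuals, and iterative reference-library
  growth to closure;
- **gene_model / splice** — a 16-exon gene model (mature mRNA from 14
  exons, start codon in exon 3, stop 147 bp into exon 16), transcript-to-
  genomic block alignment, splice-event classification (`exon_skip`,
  `alt_3ss`, `alt_5ss`, `intron_retention`, `micro_insertion`), protein
  consequences (inserted residues, premature stops, ITIM counts, soluble-
  isoform candidates), splice-site motif screening (GT→GC donors, cryptic
  stops 3 nt into the post-stem intron), and the cross-species shared-event
  filter (≥ 2 animals and ≥ 2 species);
- **phylo / nomenclature** — Jukes–Cantor
  (d = −¾ ln(1 − 4p/3)), Tamura–Nei (TN93), and Nei–Gojobori nonsynonymous
  distances; Saitou–Nei neighbor joining with deterministic tie-breaking;
  column-resampling bootstrap; lineage delimitation as maximal supported
  clades; and the `Mamu-LILRB1*001:01:01:01` four-field name grammar with
  the `Sp` splice-variant suffix;
- **diversity** — per-position amino-acid variability, per-exon
  synonymous/nonsynonymous density normalized to exon coding length,
  D1/D2 domain-identity sharing, residue-frequency tables;
- **synthetic** — a generator for lineage-structured allele sets, isoform
  mixtures, and barcoded error-bearing CCS reads with full ground truth, so
  every stage is verifiable at desk scale.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1, consensus error rate 0.001) and write their tables under
`results/`:

```bash
python analysis/01_simulate.py
python analysis/02_filter_demux.py
python analysis/03_call_alleles.py
python analysis/04_splice_events.py
python analysis/05_phylo_lineages.py
python analysis/06_diversity.py
```

Output of the first three stages:

```
12 alleles in 3 lineages; 10000 reads (1524 canonical, 8476 alternatively spliced)
10000 reads in, 8984 passed rq >= 0.99, 8984 demultiplexed, 0 unassigned
library grew to 76 transcripts in 2 iterations; 75 confirmed novel
alleles recovered: 12/12; false novels: 0
```

Most reads represent alternatively spliced transcripts (as in the real
transcriptomes), yet discovery starting from a single-entry seed library
recovers all 12 simulated alleles with no spurious novel calls. Stage 5
builds the NJ tree with 1,000 bootstrap replicates and delimits exactly the
three simulated lineages (all with support 1.0), assigning names such as
`Mamu-LILRB1*001:04:01:01`; stage 4 classifies 280 event observations into
five distinct shared splice events at exons 10 and 15 (the 3-bp acceptor
insertions, exon-15 skipping, the 30-bp intron-15 retention producing a
156-bp exon 15, and the frameshifting micro-insertion); stage 6 reports
elevated nonsynonymous density in the Ig-domain exons relative to exon
length.

The same stages are available programmatically (see `lilrseq.pipeline.
run_pipeline`) and through the `lilrseq` command-line tool
(`simulate`, `filter`, `demux`, `tree`, `run`).

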