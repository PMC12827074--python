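# Methods

## Gene model

Genes are modeled as ordered exons with half-open genomic spans (0-based
internally; 1-based inclusive in reports) and per-exon coding sub-spans.
The canonical LILRB1 model has 16 exons; exons 1–2 do not contribute to the
mature mRNA, translation starts after a 30-bp 5′UTR in exon 3 and ends
147 bp into exon 16. Exon numbering follows the genomic frame (exon 1 =
first genomic exon) even though amplicons start at exon 3/4, because every
statement about the biology ("exon 9", "exon 15") uses that frame. LILRB2's
exon 1 and intron 1 cannot be resolved in public assemblies, so LILRB2
models begin at exon 2; its long intron 1 is represented at desk scale by a
400-bp placeholder in the synthetic fixture.

Domain assignment maps exons 5–8 to D1–D4, 9–10 to the stem, 11 to the TM
segment, and 12–16 to the cytoplasmic tail. ITIM motifs are counted with
the classical consensus (S/I/V/L)-x-Y-x-x-(I/V/L) scanned over the
translated tail; the literature counts "three to four" ITIMs without
stating a motif definition, so the classical consensus is an assumption,
not an inference. The canonical fixture encodes exactly four ITIMs, one
each in exons 13–16, so exon-15 skipping reduces the count to three.

Exon 15 is modeled at 126 bp. Published descriptions mention both a 156-bp
exon 15 (after ~30 bp intron retention) and a 126-bp alternative-site form;
the fixtures use 126 bp as canonical so that the retention arithmetic
(126 + 30 = 156) is explicit. This choice is surfaced here because the
source material is ambiguous about which length is "canonical".

### Fixture phase engineering

Two reported protein consequences constrain the reading-frame phases of the
canonical fixtures, and the fixtures are constructed to satisfy them
exactly:

- An alternative 3′-ss at exon 10 inserting 3 bp adds **alanine** in
  LILRB1. An inserted trinucleotide retained from the intron must end in
  the obligatory acceptor AG, so a phase-0 acceptor could only insert
  x-A-G codons (never Ala = GCN). The LILRB1 exon-10 acceptor therefore
  sits at codon phase 1 with the last coding base of exon 9 fixed to G:
  retaining CAG yields G|CA = GCA (Ala) and leaves the following codon
  unchanged. Consequently LILRB1 exon 9 is 46 bp and exon 10 is 53 bp.
- The same +3 event inserts **glutamine** at exon 15 (both genes) and at
  exon 10 of LILRB2; those acceptors sit at phase 0, where the retained
  CAG is read directly as Gln. LILRB2's exons 9 (45 bp) and 10 (54 bp) are
  phase-0 and multiples of 3, so skipping either or both is
  frame-preserving (the shortened-stem isoforms).
- Exon 10's interior is chosen so that the +1/+2 frameshifts caused by
  micro-insertions at its acceptor encounter a stop codon within the stem,
  upstream of the TM exon — the configuration that makes these isoforms
  candidate soluble receptors.
- The first 30 bp of intron 15 are stop-free in frame with an alternative
  GT donor at +30, so the ~30-bp partial retention translates through into
  exon 16 and yields a 156-bp exon-15 block.

## Splice-event taxonomy and classification

An isoform is a list of events relative to the mature exon chain:
`exon_skip`, `alt_3ss` (acceptor shift; positive = inserted intronic
bases), `alt_5ss` (donor-side truncation, negative), `intron_retention`
(donor-side extension, positive; a full-length retention fuses adjacent
exons), and `micro_insertion` (+1/+2 at an acceptor). Classification reads
these events off a chain of maximal exact blocks produced by greedy
anchored matching of the transcript against its genomic allele (20-bp
anchors; strict by default, with an optional per-transcript substitution
budget for error-bearing reads; residual mismatches within 20 bp of a
junction are not bridged). Junction placement at repeats is normalized by
preferring annotated exon boundaries and left-aligning remaining ties.

Two disambiguation rules are package conventions where the descriptions in
the field are loose: donor-side *extensions* are always intron retention
(the reported 30-bp exon-15 events are retentions), and acceptor-side
insertions are `micro_insertion` for +1/+2, `alt_3ss` up to a 50-bp bound,
and retention beyond it. The simulator and the classifier share one event
algebra, so round-tripping (simulate → align → classify) is exact over the
isoform catalog and all pairwise combinations.

Event identity for cross-animal sharing is the tuple (kind, exon,
delta_bp), irrespective of allele, and the shared-event filter retains
events seen in at least two animals **and** at least two species.

## Allele discovery

Read assignment reproduces the strict mapping contract: a read is assigned
iff it matches a reference with zero mismatches over its full length
(≥ 400 bp) at 100% identity, tolerating at most one ambiguous base; reads
hitting several references are flagged ambiguous and excluded from support
counts. Unassigned reads are deduplicated and clustered by single linkage
at ≥ 99.5% identity over ≥ 90% mutual overlap (banded edit distance via
edlib; greedy attachment to abundance-ranked representatives followed by a
representative-level linkage closure, which is equivalent to full single
linkage at consensus error rates). Contigs with fewer than three reads are
discarded.

Because the consensus error model is substitution-only, a sequence observed
more than once inside a cluster is treated as a real haplotype/isoform
rather than noise: each attested sequence becomes its own candidate, with
singleton (error-bearing) reads attached to their nearest anchor. Clusters
with no repeated sequence fall back to weighted majority-rule consensus.
This prevents two genuinely distinct same-length isoforms (e.g. the +3
insertions at exon 10 vs exon 15) from being averaged into a chimeric
consensus.

Candidates are confirmed when their consensus is seen in two independent
runs for one individual or in at least two individuals; confirmed alleles
join the library (version bump) and matching repeats to closure (at most 5
rounds — the re-matching loop is this package's interpretation of the
"fine tuning iterate up to 5 times" mapping setting, which has no public
algorithmic definition). Before admission, a candidate identical in length
to a library sequence and within the clustering identity band of it is
rejected as a residual-error shadow of that allele; splice isoforms and
indel alleles change the length and are never suppressed by this guard. A
same-length novel allele discovered in a *later* round than a neighbor
within 0.5% identity would be suppressed — a deliberate trade against
error-driven false novels.

cDNA/gDNA reconciliation links a transcript to a genomic allele iff the
transcript is derivable from it under the gene model with a valid splice
signature; transcripts matching none are flagged transcript-only, matches
to several genomic alleles are flagged ambiguous.

## Distances, trees, lineages, names

Jukes–Cantor: d = −¾ ln(1 − 4p/3) over ungapped columns (pairwise
deletion; saturated at p ≥ ¾). Tamura–Nei: TN93 with base frequencies
estimated from the sequence pair and transitions split by purine/
pyrimidine class; it reduces to the K2P transversion term for
transversion-only divergence at uniform composition, and is cross-checked
against an independent reference implementation on frozen sequence pairs.
Nei–Gojobori: synonymous site fractions per codon position (changes to
stops count as nonsynonymous), pathway-averaged synonymous/nonsynonymous
differences over all shortest codon paths (paths through stops excluded),
and Jukes–Cantor correction of pN.

Neighbor joining follows the Saitou–Nei Q-criterion; ties are broken by the
lexicographically smallest pair of cluster representative labels, and
negative branch lengths are clamped to zero with the deficit moved to the
sister branch. Bootstrap support is column resampling with replacement
(default 1,000 replicates, seeded), with clade frequencies evaluated on the
reference tree's bipartitions; the JC path is vectorized so 1,000
replicates on a dozen alleles take seconds.

Lineages are maximal clades with bootstrap support ≥ 0.7 whose internal
pairwise divergence is ≤ 0.04 substitutions/site (JC). Neither threshold is
given in the source material; both are exposed as parameters, and the
defaults separate the simulated lineages (intra ≈ 0.02, inter ≈ 0.10)
cleanly. Singleton lineages are allowed. Name fields are assigned by
classifying each allele against its lineage's reference allele: any
nonsynonymous difference opens a new field-2 value, synonymous coding
differences field 3, non-coding-only differences field 4. The taxon prefix
combines the first two letters of the genus with the first two of the
species epithet (Macaca mulatta → Mamu, Papio hamadryas → Paha).

## Diversity statistics

Variability is the count of unique residues per aligned column, gaps
excluded by default. Per-exon S/NS densities classify each distinct
observed codon against the column's majority (consensus) codon — the
source figures never name a reference allele, and the consensus is
symmetric and reproducible; multi-position changes within one codon count
as a single event classified by the net residue effect. Counts are
normalized by exon coding length. Domain sharing partitions alleles by
exact deduced peptide identity over chosen exon sets (D1 = exon 5, D2 =
exon 6, D1–D2), flagging cross-species groups. Residue-frequency tables
report per-position counts/frequencies and the invariant positions, and
can be rendered as bar/stacked-bar plots.

## Synthetic data: what it emulates, and what it does not

The generator draws lineage founders from a canonical ancestor at 0.05
substitutions/site and alleles from founders at 0.01 (a 5× ratio), with
substitutions excluded from functional landmarks (start/stop codons,
splice dinucleotides, the engineered acceptor/donor motifs, ITIM codons)
and never creating in-frame stops. Designated lineages carry the 21-bp
exon-9 insert (default codons spell PTTGPTS; the published datum is the
peptide, the codon choice is the generator's), the GT→GC donor after exon
15, or the cryptic stop 3 nt into the post-stem intron. Samples receive
diploid genotypes (≤ 2 alleles); reads are drawn from a per-gene isoform
mixture dominated by non-canonical transcripts, carry independent
per-base substitution errors (default 0 or 10⁻³), dual 16-bp barcodes
(pairwise Hamming distance ≥ 5), random orientation, and a read-quality
mixture with 90% of reads at rq ≥ 0.99. Default scale is 20 samples ×
500 reads over 3 × 4 alleles — large enough for every allele to be
confirmable, small enough to run in seconds.

Not emulated: indel sequencing errors (the exact-match contract is the
point; an indel-bearing error model would defeat the length-based
novel/shadow discrimination and is out of scope), PCR chimeras, polymerase
pass structure, coverage biases, and recombinant alleles. Passing tests
therefore demonstrate the pipeline's logic under the stated error model,
not robustness to indel-rich platforms.

## Numerical and degenerate-input choices

Distances raise a saturation error rather than returning NaN silently; NJ
refuses matrices with saturated entries. Alignment anchors are 20 bp;
transcripts shorter than one anchor, or junctions within 20 bp of the
transcript end, are not resolvable. Empty alignments, empty FASTA
libraries, single-allele lineage assignment, and zero-replicate bootstraps
are all defined (empty outputs or singletons, never crashes). All
randomness flows from a single integer seed per run; identical
configuration and seed reproduce byte-identical FASTQ, tables, and
reports.

## Problem sizes

The test suite and the analysis scripts run the full study at 20 × 500
reads (10,000 reads, ~23 Mb of sequence), chosen so the complete discovery
loop with errors finishes in a few seconds while still giving every allele
dozens of error-free reads; bootstrap examples use 50–1,000 replicates on
12-allele alignments of ~2 kb.
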