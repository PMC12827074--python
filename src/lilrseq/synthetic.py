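"""Synthetic study generator: allele libraries, isoform mixtures, CCS reads.

The generator emulates the statistical structure of barcoded long-read
amplicon sequencing of *LILRB1*/*LILRB2*: lineage-structured allele sets
(inter-lineage divergence well above intra-lineage), per-sample diploid
genotypes, splice-isoform mixtures dominated by non-canonical transcripts,
16-bp dual sample barcodes, and a low consensus-read substitution error
rate with a read-quality tag mixture around the 0.99 filtering threshold.

A :class:`TruthSet` records every simulated allele, genotype, and per-read
(sample, allele, isoform) assignment so each downstream pipeline stage can
be scored against ground truth.

The canonical gene fixtures are constructed so that the documented splice
consequences hold by design: the LILRB1 exon-10 acceptor sits at codon
phase 1 behind a G so that a +3 bp alternative 3'-ss (CAG) inserts exactly
one alanine; exon 15 (126 bp) and the LILRB2 exon-10 acceptor sit at phase
0 so +3 bp CAG inserts a glutamine; translation ends 147 bp into exon 16;
and the cytoplasmic tail encodes four ITIM motifs, exactly one in exon 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .gene_model import (
    GeneModel,
    ITIM_RE,
    STOP_CODONS,
    build_canonical_model,
    extract_cds,
    translate_cds,
)
from .records import AlleleRecord
from .splice import SpliceEvent, apply_signature, parse_signature, parts_to_seq

# 21-bp exon-9 insertion: seven in-frame codons for the stem extension PTTGPTS
DEFAULT_INSERT_21BP = "CCAACCACCGGACCCACCTCG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_PREFERRED_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC", "Q": "CAG",
    "E": "GAA", "G": "GGC", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAG",
    "M": "ATG", "F": "TTC", "P": "CCA", "S": "TCC", "T": "ACC", "W": "TGG",
    "Y": "TAC", "V": "GTG",
}
_NONSTOP_CODONS = sorted(
    "".join(c)
    for c in __import__("itertools").product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)

# exon lengths (bp), keyed by the paper's genomic exon numbering
LILRB1_EXON_LENGTHS = {
    1: 80, 2: 120, 3: 78, 4: 36, 5: 294, 6: 294, 7: 294, 8: 294,
    9: 46, 10: 53, 11: 75, 12: 60, 13: 96, 14: 102, 15: 126, 16: 447,
}
# LILRB2: exon 1 / intron 1 unresolved in assemblies -> model starts at exon 2;
# exons 9/10 are phase-0 (skipping either or both stays in frame)
LILRB2_EXON_LENGTHS = {
    2: 120, 3: 78, 4: 36, 5: 294, 6: 294, 7: 294, 8: 294,
    9: 45, 10: 54, 11: 75, 12: 60, 13: 96, 14: 102, 15: 126, 16: 447,
}
UTR5_LEN = 30  # 5'UTR within exon 3
STOP_OFFSET_EXON16 = 147

# aa positions (0-based, in the 654-residue canonical protein) of the four
# ITIM motifs; one each in exons 13, 14, 15, 16
ITIM_AA_STARTS = (505, 540, 575, 615)
ITIM_PEPTIDES = ("VTYAQL", "SIYATL", "VTYAEV", "SVYATL")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _rand_nonstop_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n)]


def _encode(peptide: str) -> list[str]:
    return [_PREFERRED_CODON[a] for a in peptide]


def _build_cds(rng: np.random.Generator, gene: str) -> str:
    """Canonical coding sequence: 654 aa + stop, ITIMs placed, accidental
    ITIM matches scrubbed, and (LILRB1) the exon-9 terminal G enforced."""
    n_aa = 654
    codons = ["ATG"] + _rand_nonstop_codons(rng, n_aa - 1) + ["TAA"]
    for start, pep in zip(ITIM_AA_STARTS, ITIM_PEPTIDES):
        codons[start : start + 6] = _encode(pep)
    if gene == "LILRB1":
        # codon 435 spans the exon 9/10 junction (phase 1); its first base is
        # the last coding base of exon 9 and must be G for the Ala insert
        codons[435] = "GAC"
        stem_block = slice(436, 440)
    else:
        stem_block = slice(435, 439)
    # exon-10 interior chosen so that +1/+2 frameshifts (micro-insertions at
    # the exon-10 acceptor) hit a stop codon within the stem, upstream of the
    # TM exon, as described for the candidate soluble isoforms
    codons[stem_block] = ["CAT", "AAC", "CTG", "ACA"]
    designated = set(ITIM_AA_STARTS)
    while True:
        prot = translate_cds("".join(codons))
        extra = [m.start() for m in ITIM_RE.finditer(prot) if m.start() not in designated]
        if not extra:
            break
        for pos in extra:
            codons[pos + 2] = "TTC"  # break the motif's tyrosine
    return "".join(codons)


def _intron_lengths(rng: np.random.Generator, exon_indices: list[int]) -> dict[int, int]:
    out = {}
    for i in exon_indices[:-1]:
        out[i] = 400 if i == 1 else int(rng.integers(150, 300))
    return out


def _build_intron(
    rng: np.random.Generator, length: int, *, gc_donor: bool = False,
    stop_free_head: bool = False, cryptic_stop: bool = False,
    tail_alt_acceptor: bool = False,
) -> str:
    """Random intron with canonical GT..AG ends and optional special features."""
    donor = "GC" if gc_donor else "GT"
    if stop_free_head:
        # first 30 nt readable in frame without a stop, alt donor GT at +30
        head = donor + "G" + "".join(_rand_nonstop_codons(rng, 9)) + "GT"
        body = _rand_seq(rng, length - len(head) - 5)
    elif cryptic_stop:
        head = donor + "A" + "TGA"
        body = _rand_seq(rng, length - len(head) - 5)
    else:
        head = donor + "A"
        body = _rand_seq(rng, length - len(head) - 5)
        while body[:3] in STOP_CODONS:
            body = _rand_seq(rng, 3) + body[3:]
    tail = "AGCAG" if tail_alt_acceptor else _rand_seq(rng, 3) + "AG"
    return head + body + tail


def canonical_fixture(
    gene: str = "LILRB1",
    seed: int = 11,
    *,
    species: str = "Mamu",
    name: str | None = None,
    gc_donor_after_exon15: bool = False,
    cryptic_stop_after_stem: bool = False,
) -> AlleleRecord:
    """Deterministic canonical genomic allele with its gene model."""
    rng = np.random.default_rng(seed)
    exon_lengths = LILRB1_EXON_LENGTHS if gene == "LILRB1" else LILRB2_EXON_LENGTHS
    idxs = sorted(exon_lengths)
    intron_lengths = _intron_lengths(rng, idxs)
    cds = _build_cds(rng, gene)
    # distribute coding sequence over exons
    exon_seqs: dict[int, str] = {}
    off = 0
    for i in idxs:
        ln = exon_lengths[i]
        if i < 3:
            exon_seqs[i] = _rand_seq(rng, ln)
        elif i == 3:
            coding = ln - UTR5_LEN
            exon_seqs[i] = _rand_seq(rng, UTR5_LEN) + cds[off : off + coding]
            off += coding
        elif i == 16:
            exon_seqs[i] = cds[off : off + STOP_OFFSET_EXON16] + _rand_seq(
                rng, ln - STOP_OFFSET_EXON16
            )
            off += STOP_OFFSET_EXON16
        else:
            exon_seqs[i] = cds[off : off + ln]
            off += ln
    assert off == len(cds)
    intron_seqs: dict[int, str] = {}
    stem_last = 10
    for i in idxs[:-1]:
        intron_seqs[i] = _build_intron(
            rng,
            intron_lengths[i],
            gc_donor=(i == 15 and gc_donor_after_exon15),
            stop_free_head=(i == 15),
            cryptic_stop=(i == stem_last and cryptic_stop_after_stem),
            tail_alt_acceptor=(i in (9, 14)),
        )
    model = build_canonical_model(
        gene,
        exon_lengths,
        intron_lengths,
        first_mrna_exon=3,
        start_codon_offset=UTR5_LEN,
        stop_codon_offset=STOP_OFFSET_EXON16,
        itim_exon_counts={13: 1, 14: 1, 15: 1, 16: 1},
    )
    rec = AlleleRecord(
        name=name or f"{species}-{gene}*canonical",
        seq="",
        gene=gene,
        species=species,
        source="simulated",
        kind="genomic",
        model=model,
        exon_seqs=exon_seqs,
        intron_seqs=intron_seqs,
    )
    rec.rebuild_seq()
    return rec


# -- configuration --------------------------------------------------------

def default_splice_profile(gene: str) -> dict[str, float]:
    """Isoform mixture weights; non-canonical transcripts dominate, with
    exon 10 and exon 15 the most affected, as observed in the study system."""
    if gene == "LILRB1":
        return {
            "": 0.15,
            "alt_3ss:10:+3": 0.30,
            "exon_skip:15:+0": 0.20,
            "alt_3ss:10:+3;exon_skip:15:+0": 0.15,
            "alt_3ss:15:+3": 0.08,
            "intron_retention:15:+30": 0.07,
            "micro_insertion:10:+1": 0.05,
        }
    return {
        "": 0.20,
        "exon_skip:9:+0": 0.30,
        "exon_skip:9:+0;exon_skip:10:+0": 0.10,
        "alt_3ss:10:+3": 0.20,
        "exon_skip:9:+0;alt_3ss:10:+3": 0.10,
        "exon_skip:9:+0;alt_3ss:15:+3": 0.10,
    }


@dataclass
class SimConfig:
    seed: int = 0
    gene: str = "LILRB1"
    species: str = "Mamu"
    n_lineages: int = 3
    alleles_per_lineage: int = 4
    inter_lineage_divergence: float = 0.05  # substitutions/site, ancestor->founder
    intra_lineage_divergence: float = 0.01  # founder->allele
    n_samples: int = 20
    reads_per_sample: int = 500
    alleles_per_sample: int = 2
    n_runs: int = 2
    ccs_error_rate: float = 0.0
    barcode_len: int = 16
    min_barcode_dist: int = 5
    rq_pass_frac: float = 0.9
    splice_profile: dict[str, float] | None = None
    insert_exon: int = 9
    insert_seq: str = DEFAULT_INSERT_21BP
    insert_lineages: tuple[int, ...] = (0,)
    gc_donor_lineages: tuple[int, ...] = (0, 1)
    cryptic_stop_lineages: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        profile = self.splice_profile or default_splice_profile(self.gene)
        if abs(sum(profile.values()) - 1.0) > 1e-9:
            raise ValueError("splice profile weights must sum to 1")
        self.splice_profile = profile
        if self.inter_lineage_divergence <= self.intra_lineage_divergence:
            raise ValueError("inter-lineage divergence must exceed intra-lineage")
        if self.barcode_len <= 0:
            raise ValueError("barcode_len must be positive")
        if self.insert_lineages and len(self.insert_seq) % 3 != 0:
            raise ValueError(
                "an in-frame insert must have length divisible by 3"
            )


@dataclass
class TruthSet:
    config: SimConfig
    alleles: list[AlleleRecord]
    genotypes: dict[str, list[str]]
    barcodes: pd.DataFrame  # sample, fwd_barcode, rev_barcode
    cds_alignment: dict[str, str]
    reads: pd.DataFrame | None = None  # per-read truth, filled by simulate_ccs_reads
    transcripts: dict[tuple[str, str], str] = field(default_factory=dict)

    def allele(self, name: str) -> AlleleRecord:
        for rec in self.alleles:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def transcript(self, allele_name: str, signature: str) -> str:
        key = (allele_name, signature)
        if key not in self.transcripts:
            rec = self.allele(allele_name)
            self.transcripts[key] = simulate_isoform(rec, parse_signature(signature))
        return self.transcripts[key]

    def all_transcripts(self) -> dict[tuple[str, str], str]:
        for rec in self.alleles:
            for sig in self.config.splice_profile:
                self.transcript(rec.name, sig)
        return self.transcripts


# -- allele simulation ----------------------------------------------------

def _protected_positions(rec: AlleleRecord) -> np.ndarray:
    """Boolean mask over the genomic sequence of positions that must not be
    mutated: start/stop codons, splice dinucleotides, engineered acceptor/
    donor motifs, the cryptic-stop window, ITIM codons, and the LILRB1
    exon-9 terminal G."""
    model = rec.model
    mask = np.zeros(len(rec.seq), dtype=bool)
    s, _ = model.coding_span(model.start_codon_exon)
    mask[s : s + 3] = True
    _, e = model.coding_span(model.stop_codon_exon)
    mask[e - 3 : e] = True
    idxs = model.exon_indices
    for i in idxs[:-1]:
        a, b = model.intron_span(i)
        mask[a : a + 2] = True
        mask[b - 2 : b] = True
        if i in (9, 14):
            mask[b - 5 : b] = True
        if i == 15:
            mask[a : a + 32] = True
        if i == max(model.stem_exons):
            mask[a : a + 6] = True
    # ITIM codons, via the coding->genomic map
    g_of_c: list[int] = []
    for ex in model.mature_exons():
        a, b = model.coding_span(ex.index)
        g_of_c.extend(range(a, b))
    for start in ITIM_AA_STARTS:
        for c in range(3 * start, 3 * start + 18):
            mask[g_of_c[c]] = True
    if rec.gene == "LILRB1":
        _, e9 = model.coding_span(9)
        mask[e9 - 1] = True
    return mask


def _mutate(
    rec: AlleleRecord, rate: float, rng: np.random.Generator, name: str
) -> AlleleRecord:
    """Substitution-only divergence avoiding protected sites and avoiding the
    creation of in-frame internal stop codons."""
    model = rec.model
    seq = np.frombuffer(rec.seq.encode(), dtype="S1").copy()
    mask = _protected_positions(rec)
    g_of_c: list[int] = []
    for ex in model.mature_exons():
        a, b = model.coding_span(ex.index)
        g_of_c.extend(range(a, b))
    codon_of_g = {g: c // 3 for c, g in enumerate(g_of_c)}
    codon_positions = [g_of_c[3 * k : 3 * k + 3] for k in range(len(g_of_c) // 3)]
    free = np.flatnonzero(~mask)
    n_mut = rng.binomial(free.size, rate)
    sites = rng.choice(free, size=n_mut, replace=False)
    for pos in sites:
        current = seq[pos]
        choices = [b for b in b"ACGT" if b != ord(current)]
        rng.shuffle(choices)
        for b in choices:
            old = seq[pos]
            seq[pos] = bytes([b])
            k = codon_of_g.get(int(pos))
            if k is not None:
                codon = b"".join(seq[p] for p in codon_positions[k]).decode()
                if codon in STOP_CODONS:
                    seq[pos] = old
                    continue
            break
    mutated = seq.tobytes().decode()
    # re-split into exon/intron segments (lengths unchanged)
    exon_seqs = {ex.index: mutated[ex.start : ex.end] for ex in model.exons}
    intron_seqs = {}
    for i in model.exon_indices[:-1]:
        a, b = model.intron_span(i)
        intron_seqs[i] = mutated[a:b]
    out = AlleleRecord(
        name=name, seq=mutated, gene=rec.gene, species=rec.species,
        source="simulated", kind="genomic", model=model,
        exon_seqs=exon_seqs, intron_seqs=intron_seqs,
    )
    return out


def _apply_insert(rec: AlleleRecord, exon: int, insert: str, offset: int = 24) -> None:
    """In-frame insertion inside an exon; rebuilds the allele's own model."""
    old = rec.exon_seqs[exon]
    rec.exon_seqs[exon] = old[:offset] + insert + old[offset:]
    model = rec.model
    exon_lengths = {ex.index: ex.length for ex in model.exons}
    exon_lengths[exon] += len(insert)
    intron_lengths = {i: model.intron_span(i)[1] - model.intron_span(i)[0]
                      for i in model.exon_indices[:-1]}
    rec.model = build_canonical_model(
        model.gene_name, exon_lengths, intron_lengths,
        first_mrna_exon=model.start_codon_exon,
        start_codon_offset=model.exon(model.start_codon_exon).coding_start,
        stop_codon_offset=model.exon(model.stop_codon_exon).coding_prefix_len,
        itim_exon_counts=dict(model.itim_exon_counts),
    )
    rec.meta["insert"] = (exon, offset, len(insert))
    rec.rebuild_seq()


def simulate_allele_set(config: SimConfig) -> TruthSet:
    """Star-within-star allele simulation: ancestor -> lineage founders ->
    alleles, with configured structural features on designated lineages."""
    rng = np.random.default_rng(config.seed)
    founders = []
    for l in range(config.n_lineages):
        ancestor = canonical_fixture(config.gene, seed=11, species=config.species)
        if l in config.gc_donor_lineages:
            ancestor.intron_seqs[15] = "GC" + ancestor.intron_seqs[15][2:]
        if l in config.cryptic_stop_lineages:
            i10 = max(ancestor.model.stem_exons)
            seq = ancestor.intron_seqs[i10]
            ancestor.intron_seqs[i10] = seq[:3] + "TGA" + seq[6:]
        ancestor.rebuild_seq()
        founders.append(_mutate(
            ancestor, config.inter_lineage_divergence, rng,
            f"{config.species}-{config.gene}*{l + 1:03d}",
        ))
    alleles: list[AlleleRecord] = []
    seen = set()
    for l, founder in enumerate(founders):
        for a in range(config.alleles_per_lineage):
            name = f"{config.species}-{config.gene}*{l + 1:03d}:{a + 1:02d}"
            for _ in range(20):
                rec = _mutate(founder, config.intra_lineage_divergence, rng, name)
                if rec.seq not in seen:
                    break
            seen.add(rec.seq)
            rec.lineage = f"{l + 1:03d}"
            if l in config.insert_lineages:
                _apply_insert(rec, config.insert_exon, config.insert_seq)
            alleles.append(rec)
    # genotypes: <=2 alleles per gene per individual (diploid)
    names = [rec.name for rec in alleles]
    genotypes = {}
    for s in range(config.n_samples):
        pair = rng.choice(len(names), size=config.alleles_per_sample, replace=True)
        genotypes[f"S{s + 1:02d}"] = sorted({names[i] for i in pair})
    barcodes = _make_barcodes(rng, list(genotypes), config)
    return TruthSet(
        config=config,
        alleles=alleles,
        genotypes=genotypes,
        barcodes=barcodes,
        cds_alignment=_truth_cds_alignment(alleles, config),
    )


def _truth_cds_alignment(alleles: list[AlleleRecord], config: SimConfig) -> dict[str, str]:
    """Coordinate-exact CDS alignment (gap columns at the configured insert)."""
    out = {}
    has_insert = {rec.name: "insert" in rec.meta for rec in alleles}
    any_insert = any(has_insert.values())
    for rec in alleles:
        cds = extract_cds(rec.model, rec.seq)
        if any_insert and not has_insert[rec.name]:
            pos = rec.model.coding_length_before(config.insert_exon) + 24
            cds = cds[:pos] + "-" * len(config.insert_seq) + cds[pos:]
        out[rec.name] = cds
    assert len({len(v) for v in out.values()}) == 1
    return out


def _make_barcodes(
    rng: np.random.Generator, samples: list[str], config: SimConfig
) -> pd.DataFrame:
    rows = []
    chosen: list[str] = []

    def draw() -> str:
        while True:
            bc = _rand_seq(rng, config.barcode_len)
            if all(
                sum(a != b for a, b in zip(bc, other)) >= config.min_barcode_dist
                for other in chosen
            ):
                chosen.append(bc)
                return bc

    for s in samples:
        rows.append({"sample": s, "fwd_barcode": draw(), "rev_barcode": draw()})
    return pd.DataFrame(rows)


# -- isoforms and reads ---------------------------------------------------

def simulate_isoform(allele: AlleleRecord, signature: list[SpliceEvent]) -> str:
    """Deterministic spliced transcript for an allele and event signature."""
    if allele.model is None:
        raise ValueError("allele lacks an exon model")
    return parts_to_seq(
        apply_signature(allele.model, allele.exon_seqs, allele.intron_seqs, signature)
    )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def simulate_ccs_reads(truth: TruthSet, config: SimConfig | None = None):
    """Draw barcoded, error-bearing consensus reads per sample.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence, rq)`` and ``truth.reads`` holds the per-read truth
    manifest. Fully reproducible from the config seed.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    profile = config.splice_profile
    sigs = list(profile)
    weights = np.array([profile[s] for s in sigs])
    bc = truth.barcodes.set_index("sample")
    reads = []
    rows = []
    for sample, genotype in truth.genotypes.items():
        fwd = bc.loc[sample, "fwd_barcode"]
        rev_rc = _revcomp(bc.loc[sample, "rev_barcode"])
        for r in range(config.reads_per_sample):
            allele = genotype[rng.integers(0, len(genotype))]
            sig = sigs[rng.choice(len(sigs), p=weights)]
            tx = truth.transcript(allele, sig)
            n_err = rng.binomial(len(tx), config.ccs_error_rate)
            if n_err:
                arr = np.frombuffer(tx.encode(), dtype="S1").copy()
                for pos in rng.choice(len(tx), size=n_err, replace=False):
                    alts = [b for b in b"ACGT" if b != ord(arr[pos])]
                    arr[pos] = bytes([alts[rng.integers(0, 3)]])
                tx = arr.tobytes().decode()
            seq = fwd + tx + rev_rc
            flipped = bool(rng.integers(0, 2))
            if flipped:
                seq = _revcomp(seq)
            if rng.random() < config.rq_pass_frac:
                rq = 0.99 + 0.00999 * rng.random()
            else:
                rq = 0.90 + 0.089 * rng.random()
            run = f"run{r % config.n_runs + 1}"
            read_id = f"{sample}_{r:05d}"
            reads.append((read_id, seq, round(rq, 5)))
            rows.append(
                {
                    "read_id": read_id, "sample": sample, "allele": allele,
                    "signature": sig, "n_errors": int(n_err), "rq": round(rq, 5),
                    "run": run, "flipped": flipped,
                }
            )
    truth.reads = pd.DataFrame(rows)
    return reads, truth


# -- text I/O -------------------------------------------------------------

def write_allele_fasta(alleles: list[AlleleRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in alleles:
            fh.write(f">{rec.name}|{rec.gene}|{rec.species}|{rec.source}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")


def write_fastq(reads, path) -> None:
    """FASTQ with the read quality as an ``rq=`` comment tag."""
    with open(path, "w") as fh:
        for read_id, seq, rq in reads:
            fh.write(f"@{read_id} rq={rq:.5f}\n{seq}\n+\n{'I' * len(seq)}\n")
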