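"""Exon-intron architecture of LILRB-family genes.

LILRB1 consists of 16 exons of which 14 encode the mature mRNA; translation
starts in exon 3 and terminates at the beginning of exon 16, 147 bp in. The
four extracellular Ig-like domains D1-D4 are encoded by exons 5-8, the stem
(spacer) region by exons 9-10, the transmembrane segment by exon 11, and the
ITIM-bearing cytoplasmic tail by exons 12-16. LILRB2 has a comparable
organization but its exon 1 (and the adjacent long intron 1) cannot be
resolved in public assemblies, so LILRB2 models start at exon 2.

Coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

# Classical immunoreceptor tyrosine-based inhibitory motif consensus
# (S/I/V/L)-x-Y-x-x-(I/V/L); overlap-tolerant scan.
ITIM_RE = re.compile(r"(?=([SIVL].Y..[IVL]))")

#: structural regions in N->C order
REGIONS = ("leader", "D1", "D2", "D3", "D4", "stem", "TM", "Cyt")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class StructuralInconsistencyError(ValueError):
    """A sequence does not fit the gene model (frame, span, or exon count)."""


@dataclass(frozen=True)
class ExonSpec:
    """One exon: 1-based index, half-open genomic span, coding sub-span.

    ``coding_start``/``coding_end`` are offsets *within* the exon; for fully
    coding exons they cover the whole span, for the terminal exon
    ``coding_end`` is the stop-codon offset (``coding_prefix_len``).
    """

    index: int
    start: int
    end: int
    coding_start: int = 0
    coding_end: int | None = None  # None -> exon end

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def coding_prefix_len(self) -> int:
        """Length of the coding portion measured from the coding start."""
        end = self.length if self.coding_end is None else self.coding_end
        return max(0, end - self.coding_start)


@dataclass
class GeneModel:
    gene_name: str
    exons: list[ExonSpec]
    mature_mrna_exons: frozenset[int]
    start_codon_exon: int
    stop_codon_exon: int
    domain_map: dict[int, str] = field(default_factory=dict)
    itim_exon_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -1
        prev_idx = 0
        for ex in self.exons:
            if ex.index <= prev_idx or ex.start < prev_end or ex.end <= ex.start:
                raise StructuralInconsistencyError(
                    f"exon {ex.index}: spans must be non-overlapping and "
                    "strictly increasing by index"
                )
            if ex.coding_prefix_len > ex.length:
                raise StructuralInconsistencyError(
                    f"exon {ex.index}: coding portion exceeds exon length"
                )
            prev_end, prev_idx = ex.end, ex.index
        if self.start_codon_exon not in self.mature_mrna_exons:
            raise StructuralInconsistencyError("start codon outside mature mRNA")

    # -- lookups ----------------------------------------------------------
    def exon(self, index: int) -> ExonSpec:
        for ex in self.exons:
            if ex.index == index:
                return ex
        raise KeyError(f"unknown exon index {index!r} for {self.gene_name}")

    def has_exon(self, index: int) -> bool:
        return any(ex.index == index for ex in self.exons)

    @property
    def exon_indices(self) -> list[int]:
        return [ex.index for ex in self.exons]

    def mature_exons(self) -> list[ExonSpec]:
        return [ex for ex in self.exons if ex.index in self.mature_mrna_exons]

    def intron_span(self, after_exon: int) -> tuple[int, int]:
        """Half-open genomic span of the intron following ``after_exon``."""
        idxs = self.exon_indices
        pos = idxs.index(after_exon)
        if pos + 1 >= len(idxs):
            raise KeyError(f"no intron after terminal exon {after_exon}")
        return self.exon(after_exon).end, self.exons[pos + 1].start

    def coding_span(self, index: int) -> tuple[int, int]:
        """Genomic span of an exon's coding portion."""
        ex = self.exon(index)
        end = ex.end if ex.coding_end is None else ex.start + ex.coding_end
        return ex.start + ex.coding_start, end

    def coding_length_before(self, index: int) -> int:
        """Total coding bp contributed by mature exons upstream of ``index``."""
        total = 0
        for ex in self.mature_exons():
            if ex.index >= index:
                break
            total += ex.coding_prefix_len
        return total

    @property
    def total_coding_length(self) -> int:
        return sum(ex.coding_prefix_len for ex in self.mature_exons())

    @property
    def stem_exons(self) -> list[int]:
        return [i for i, r in sorted(self.domain_map.items()) if r == "stem"]


def _default_domain_map(exon_indices: list[int]) -> dict[int, str]:
    """Fig-1 style region assignment: D1-D4 = exons 5-8, stem = 9-10,
    TM = 11, Cyt = 12-16; coding exons upstream of 5 are leader."""
    table = {5: "D1", 6: "D2", 7: "D3", 8: "D4", 9: "stem", 10: "stem", 11: "TM"}
    out: dict[int, str] = {}
    for i in exon_indices:
        if i in table:
            out[i] = table[i]
        elif 12 <= i <= 16:
            out[i] = "Cyt"
        elif 3 <= i < 5:
            out[i] = "leader"
    return out


def build_canonical_model(
    gene_name: str,
    exon_lengths: dict[int, int],
    intron_lengths: dict[int, int],
    *,
    first_mrna_exon: int = 3,
    start_codon_offset: int = 0,
    stop_codon_offset: int | None = None,
    domain_map: dict[int, str] | None = None,
    itim_exon_counts: dict[int, int] | None = None,
) -> GeneModel:
    """Assemble a :class:`GeneModel` from per-exon/intron lengths.

    ``exon_lengths``/``intron_lengths`` are keyed by 1-based exon index
    (intron *i* follows exon *i*). ``start_codon_offset`` is the offset of the
    ATG within the first mRNA exon; ``stop_codon_offset`` the coding prefix of
    the terminal exon (e.g. 147 for LILRB1 exon 16).
    """
    if not exon_lengths or any(v <= 0 for v in exon_lengths.values()):
        raise ValueError("exon lengths must be non-empty and positive")
    idxs = sorted(exon_lengths)
    terminal = idxs[-1]
    if stop_codon_offset is not None and stop_codon_offset > exon_lengths[terminal]:
        raise StructuralInconsistencyError(
            "declared stop offset exceeds the terminal exon length"
        )
    exons = []
    pos = 0
    for i in idxs:
        ln = exon_lengths[i]
        coding_start = 0
        coding_end: int | None = None
        if i < first_mrna_exon:
            coding_end = 0
        if i == first_mrna_exon:
            coding_start = start_codon_offset
        if i == terminal and stop_codon_offset is not None:
            coding_end = stop_codon_offset
        exons.append(ExonSpec(i, pos, pos + ln, coding_start, coding_end))
        pos += ln
        if i != terminal:
            pos += intron_lengths.get(i, 0)
    mature = frozenset(i for i in idxs if i >= first_mrna_exon)
    return GeneModel(
        gene_name=gene_name,
        exons=exons,
        mature_mrna_exons=mature,
        start_codon_exon=first_mrna_exon,
        stop_codon_exon=terminal,
        domain_map=_default_domain_map(idxs) if domain_map is None else domain_map,
        itim_exon_counts=itim_exon_counts or {},
    )


def domain_of(model: GeneModel, exon_index: int) -> str:
    """Structural region encoded by an exon (D1-D4, stem, TM, Cyt, leader)."""
    model.exon(exon_index)  # raises KeyError for unknown indices
    try:
        return model.domain_map[exon_index]
    except KeyError:
        return "UTR"


def extract_cds(model: GeneModel, genomic_seq: str) -> str:
    """Concatenated coding portions of the mature-mRNA exons.

    Starts at the start codon, ends with the stop codon in the terminal
    exon's coding prefix; the result must be in frame.
    """
    if len(genomic_seq) < model.exons[-1].end:
        raise StructuralInconsistencyError(
            f"sequence length {len(genomic_seq)} shorter than model span "
            f"{model.exons[-1].end}"
        )
    parts = []
    for ex in model.mature_exons():
        s, e = model.coding_span(ex.index)
        parts.append(genomic_seq[s:e])
    cds = "".join(parts)
    if len(cds) % 3 != 0:
        raise StructuralInconsistencyError(
            f"coding sequence length {len(cds)} not a multiple of 3"
        )
    return cds


def assemble_genomic(
    model: GeneModel, exon_seqs: dict[int, str], intron_seqs: dict[int, str]
) -> str:
    """Inverse of exon/intron decomposition: concatenate per-model segments."""
    parts = []
    idxs = model.exon_indices
    for i in idxs:
        parts.append(exon_seqs[i])
        if i != idxs[-1]:
            parts.append(intron_seqs[i])
    return "".join(parts)


def translate_cds(cds: str) -> str:
    """Translate, stopping at (and excluding) the first stop codon."""
    prot = str(Seq(cds).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


def count_itims(peptide: str) -> int:
    return len(ITIM_RE.findall(peptide))


def itim_counts_by_exon(model: GeneModel, genomic_seq: str) -> dict[int, int]:
    """ITIM motifs per exon, attributed to the exon holding the motif's
    first residue's first coding base."""
    cds = extract_cds(model, genomic_seq)
    prot = translate_cds(cds)
    # map coding offset -> exon index
    boundaries = []  # (coding_offset_start, exon_index)
    off = 0
    for ex in model.mature_exons():
        boundaries.append((off, ex.index))
        off += ex.coding_prefix_len
    counts: dict[int, int] = {}
    for m in ITIM_RE.finditer(prot):
        nt = m.start() * 3
        exon = max(i for o, i in boundaries if o <= nt)
        counts[exon] = counts.get(exon, 0) + 1
    return counts


# -- serialization --------------------------------------------------------

def model_to_table(model: GeneModel):
    """Tabular form (1-based inclusive coordinates in the report)."""
    import pandas as pd

    rows = []
    for ex in model.exons:
        rows.append(
            {
                "exon_index": ex.index,
                "start": ex.start + 1,
                "end": ex.end,
                "coding_prefix_len": ex.coding_prefix_len,
                "region": domain_of(model, ex.index),
                "itim_count": model.itim_exon_counts.get(ex.index, 0),
            }
        )
    return pd.DataFrame(rows)


def model_from_table(gene_name: str, df, *, start_codon_exon: int,
                     stop_codon_exon: int) -> GeneModel:
    exons = []
    itims = {}
    domains = {}
    for row in df.itertuples(index=False):
        start = int(row.start) - 1
        end = int(row.end)
        ln = end - start
        cpl = int(row.coding_prefix_len)
        coding_start = ln - cpl if 0 < cpl < ln and row.exon_index == start_codon_exon else 0
        coding_end = None
        if cpl == 0:
            coding_end = 0
        elif cpl < ln and row.exon_index == stop_codon_exon:
            coding_end = cpl
        exons.append(ExonSpec(int(row.exon_index), start, end, coding_start, coding_end))
        if row.itim_count:
            itims[int(row.exon_index)] = int(row.itim_count)
        if row.region not in ("UTR",):
            domains[int(row.exon_index)] = str(row.region)
    mature = frozenset(i for i in (e.index for e in exons) if i >= start_codon_exon)
    return GeneModel(gene_name, exons, mature, start_codon_exon, stop_codon_exon,
                     domains, itims)


def model_to_gff3(model: GeneModel, seqid: str) -> str:
    """Minimal GFF3 rendering (gene/exon/CDS features, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    gene_id = model.gene_name
    lines.append(
        f"{seqid}\tlilrseq\tgene\t{model.exons[0].start + 1}\t{model.exons[-1].end}"
        f"\t.\t+\t.\tID={gene_id}"
    )
    for ex in model.exons:
        lines.append(
            f"{seqid}\tlilrseq\texon\t{ex.start + 1}\t{ex.end}\t.\t+\t.\t"
            f"ID={gene_id}.exon{ex.index};Parent={gene_id}"
        )
        if ex.coding_prefix_len > 0 and ex.index in model.mature_mrna_exons:
            s, e = model.coding_span(ex.index)
            lines.append(
                f"{seqid}\tlilrseq\tCDS\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID={gene_id}.cds{ex.index};Parent={gene_id}"
            )
    return "\n".join(lines) + "\n"
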