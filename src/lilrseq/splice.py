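"""Alternative-splicing event model and transcript annotation.

An isoform is described by a *signature*: an ordered list of deviations from
the canonical mature-exon chain. Event kinds:

``exon_skip``
    a mature exon absent from the transcript (delta_bp = 0; the skipped
    length is looked up in the gene model),
``alt_3ss``
    acceptor shifted by ``delta_bp`` (positive = upstream into the preceding
    intron, i.e. inserted bases; negative = downstream into the exon),
``alt_5ss``
    donor shifted upstream into the exon (negative delta, truncation),
``intron_retention``
    exon extended contiguously into the following intron by ``delta_bp`` > 0
    (a full-length retention fuses two exons),
``micro_insertion``
    acceptor-side +1/+2 bp insertion (typically frameshifting).

Donor-side *extensions* are always classified as retention — the 30-bp
events downstream of exon 15 that yield a 156-bp exon are partial intron
retentions — while acceptor-side insertions of >= 3 bp up to a configurable
bound are alternative 3'-splice-site usage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gene_model import (
    GeneModel,
    ITIM_RE,
    STOP_CODONS,
    StructuralInconsistencyError,
    translate_cds,
)

EVENT_KINDS = ("exon_skip", "alt_3ss", "alt_5ss", "intron_retention", "micro_insertion")


class NoDerivationError(ValueError):
    """The transcript cannot be derived from the genomic allele."""


class IncompatibleEventsError(ValueError):
    """Events in a signature contradict each other."""


@dataclass(frozen=True, order=True)
class SpliceEvent:
    exon: int
    kind: str
    delta_bp: int = 0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("alt_3ss", "alt_5ss") and self.delta_bp == 0:
            raise ValueError(f"{self.kind} requires a non-zero delta")
        if self.kind == "alt_5ss" and self.delta_bp > 0:
            raise ValueError("alt_5ss is donor-side truncation (negative delta)")
        if self.kind == "intron_retention" and self.delta_bp <= 0:
            raise ValueError("intron_retention requires delta > 0")
        if self.kind == "micro_insertion" and self.delta_bp not in (1, 2):
            raise ValueError("micro_insertion delta must be +1 or +2")
        if self.kind == "exon_skip" and self.delta_bp != 0:
            raise ValueError("exon_skip carries no delta")


ACCEPTOR_KINDS = ("alt_3ss", "micro_insertion")
DONOR_KINDS = ("alt_5ss", "intron_retention")


def _check_compatible(model: GeneModel, signature: list[SpliceEvent]) -> None:
    skips = {ev.exon for ev in signature if ev.kind == "exon_skip"}
    seen: set[tuple[int, str]] = set()
    for ev in signature:
        if not model.has_exon(ev.exon) or ev.exon not in model.mature_mrna_exons:
            raise IncompatibleEventsError(f"exon {ev.exon} not in the mature mRNA")
        if ev.kind != "exon_skip" and ev.exon in skips:
            raise IncompatibleEventsError(
                f"{ev.kind} on skipped exon {ev.exon}"
            )
        side = ("acceptor" if ev.kind in ACCEPTOR_KINDS
                else "donor" if ev.kind in DONOR_KINDS else "skip")
        key = (ev.exon, side)
        if key in seen:
            raise IncompatibleEventsError(
                f"multiple {side} events on exon {ev.exon}"
            )
        seen.add(key)


def apply_signature(
    model: GeneModel,
    exon_seqs: dict[int, str],
    intron_seqs: dict[int, str],
    signature: list[SpliceEvent],
) -> list[tuple[float, str]]:
    """Splice a transcript; returns tagged parts ``(source, seq)``.

    Source tags are the exon index for exonic sequence and ``i + 0.5`` for
    bases retained from the intron following exon *i*. Concatenating the
    part sequences yields the transcript.
    """
    _check_compatible(model, signature)
    skips = {ev.exon for ev in signature if ev.kind == "exon_skip"}
    acceptor = {ev.exon: ev for ev in signature if ev.kind in ACCEPTOR_KINDS}
    donor = {ev.exon: ev for ev in signature if ev.kind in DONOR_KINDS}
    idxs = model.exon_indices
    parts: list[tuple[float, str]] = []
    for ex in model.mature_exons():
        i = ex.index
        if i in skips:
            continue
        seq = exon_seqs[i]
        if i in acceptor:
            k = acceptor[i].delta_bp
            prev = idxs[idxs.index(i) - 1]  # intron before exon i follows prev
            if k > 0:
                if k > len(intron_seqs[prev]):
                    raise IncompatibleEventsError("acceptor shift exceeds intron")
                parts.append((prev + 0.5, intron_seqs[prev][-k:]))
            else:
                seq = seq[-k:]
        if i in donor:
            ev = donor[i]
            if ev.kind == "alt_5ss":
                seq = seq[: ev.delta_bp]  # negative delta trims the 3' end
            elif ev.kind == "intron_retention":
                if ev.delta_bp > len(intron_seqs[i]):
                    raise IncompatibleEventsError("retention exceeds intron length")
                parts.append((float(i), seq))
                parts.append((i + 0.5, intron_seqs[i][: ev.delta_bp]))
                continue
        parts.append((float(i), seq))
    return parts


def parts_to_seq(parts: list[tuple[float, str]]) -> str:
    return "".join(seq for _, seq in parts)


# -- transcript -> genomic block alignment --------------------------------

@dataclass
class Block:
    """A maximal exact match: transcript[t_start:t_end] == genomic[g_start:g_end]."""

    t_start: int
    t_end: int
    g_start: int
    g_end: int

    def __len__(self) -> int:
        return self.t_end - self.t_start


def align_transcript(
    transcript: str,
    genomic: str,
    model: GeneModel | None = None,
    *,
    anchor: int = 20,
    max_mismatches: int = 0,
) -> list[Block]:
    """Partition a transcript into co-linear exact blocks on its genomic allele.

    Greedy maximal-exact-match chaining with a fixed-length anchor for
    junction re-seeding; raises :class:`NoDerivationError` when the residual
    mismatch budget is exhausted. Junctions are normalized toward annotated
    exon boundaries (left-aligned where still ambiguous) when a model is
    supplied.
    """
    if not transcript:
        raise NoDerivationError("empty transcript")
    j = genomic.find(transcript[:anchor])
    if j < 0:
        raise NoDerivationError("transcript start not found in genomic sequence")
    blocks: list[Block] = []
    i = 0
    mismatches = 0
    bt, bg = i, j
    while i < len(transcript):
        if j < len(genomic) and transcript[i] == genomic[j]:
            i += 1
            j += 1
            continue
        # tolerated substitution (sequencing error) within the block?
        if (
            mismatches < max_mismatches
            and j < len(genomic)
            and transcript[i + 1 : i + 1 + anchor] == genomic[j + 1 : j + 1 + anchor]
            and transcript[i + 1 : i + 1 + anchor]
        ):
            mismatches += 1
            i += 1
            j += 1
            continue
        blocks.append(Block(bt, i, bg, j))
        if i >= len(transcript):
            break
        nxt = genomic.find(transcript[i : i + anchor], j)
        if nxt < 0 or len(transcript) - i < anchor:
            raise NoDerivationError(
                f"transcript position {i} not derivable from the genomic allele"
            )
        bt, bg = i, nxt
        j = nxt
    if i > bt or not blocks:
        blocks.append(Block(bt, i, bg, j))
    if model is not None:
        _normalize_junctions(blocks, transcript, genomic, model)
    return blocks


def _normalize_junctions(
    blocks: list[Block], transcript: str, genomic: str, model: GeneModel
) -> None:
    """Resolve indel placement ambiguity at block junctions.

    Prefer junction placements where the donor side ends on an annotated
    exon end and/or the acceptor side starts on an annotated exon start;
    remaining ties are broken by the left-most (exon-start-ward) placement.
    """
    exon_starts = {ex.start for ex in model.exons}
    exon_ends = {ex.end for ex in model.exons}
    for a, b in zip(blocks, blocks[1:]):
        left = 0
        while (
            left < len(a)
            and transcript[a.t_end - 1 - left] == genomic[b.g_start - 1 - left]
        ):
            left += 1
        right = 0
        while (
            right < len(b)
            and b.t_start + right < len(transcript)
            and a.g_end + right < len(genomic)
            and transcript[b.t_start + right] == genomic[a.g_end + right]
        ):
            right += 1
        best_s, best_score = 0, None
        for s in range(-right, left + 1):
            score = (
                2 * ((a.g_end - s) in exon_ends)
                + 2 * ((b.g_start - s) in exon_starts)
                + s / (left + right + 1) * 1e-3
            )
            if best_score is None or score > best_score:
                best_s, best_score = s, score
        if best_s:
            a.t_end -= best_s
            a.g_end -= best_s
            b.t_start -= best_s
            b.g_start -= best_s


def classify_events(
    blocks: list[Block], model: GeneModel, *, alt_ss_bound: int = 50
) -> list[SpliceEvent]:
    """Read a splice signature off a transcript/genomic block chain."""
    mature = model.mature_exons()
    overlaps: dict[int, list[Block]] = {}
    for ex in mature:
        hit = [b for b in blocks if b.g_start < ex.end and b.g_end > ex.start]
        if hit:
            overlaps[ex.index] = hit
    events: list[SpliceEvent] = []
    for ex in mature:
        if ex.index not in overlaps:
            events.append(SpliceEvent(ex.index, "exon_skip"))
    present = [ex for ex in mature if ex.index in overlaps]
    for pos, ex in enumerate(present):
        bs = overlaps[ex.index]
        first = min(bs, key=lambda b: b.g_start)
        last = max(bs, key=lambda b: b.g_end)
        prev = present[pos - 1] if pos > 0 else None
        # acceptor side
        if prev is not None and first in overlaps.get(prev.index, []):
            # same block runs through the intervening intron: full retention
            intron_len = ex.start - prev.end
            events.append(SpliceEvent(prev.index, "intron_retention", intron_len))
        elif pos > 0 or first.g_start != ex.start:
            k = ex.start - first.g_start
            if k in (1, 2):
                events.append(SpliceEvent(ex.index, "micro_insertion", k))
            elif 0 < k <= alt_ss_bound:
                events.append(SpliceEvent(ex.index, "alt_3ss", k))
            elif k > alt_ss_bound:
                events.append(SpliceEvent(ex.index, "intron_retention", k))
            elif k < 0:
                events.append(SpliceEvent(ex.index, "alt_3ss", k))
        # donor side
        nxt = present[pos + 1] if pos + 1 < len(present) else None
        if nxt is not None and last in overlaps.get(nxt.index, []):
            continue  # handled as full retention at the next junction
        if nxt is not None or last.g_end != ex.end:
            k = last.g_end - ex.end
            if k > 0:
                events.append(SpliceEvent(ex.index, "intron_retention", k))
            elif k < 0 and nxt is not None:
                events.append(SpliceEvent(ex.index, "alt_5ss", k))
    out = sorted(set(events))
    _check_chain_consistency(blocks, model)
    return out


def _check_chain_consistency(blocks: list[Block], model: GeneModel) -> None:
    for a, b in zip(blocks, blocks[1:]):
        if a.t_end != b.t_start or b.g_start < a.g_end:
            raise StructuralInconsistencyError("block chain not co-linear")


def signature_transcript_length(model: GeneModel, signature: list[SpliceEvent]) -> int:
    """Expected transcript length: mature exons + deltas - skipped exons."""
    total = sum(ex.length for ex in model.mature_exons())
    for ev in signature:
        if ev.kind == "exon_skip":
            total -= model.exon(ev.exon).length
        else:
            total += ev.delta_bp
    return total


# -- protein consequences -------------------------------------------------

@dataclass
class IsoformAnnotation:
    signature: list[SpliceEvent]
    cds_intact: bool
    premature_stop: int | None  # aa index of the stop, if before canonical end
    itim_count: int
    inserted_residues: str | None
    soluble_candidate: bool
    protein: str


def _diff_insertion(canonical: str, observed: str) -> str | None:
    if len(observed) <= len(canonical):
        return None
    m = len(observed) - len(canonical)
    for i in range(len(canonical) + 1):
        if observed[:i] == canonical[:i] and observed[i + m :] == canonical[i:]:
            return observed[i : i + m]
        if i < len(canonical) and observed[i] != canonical[i]:
            break
    return None


def annotate_protein(
    signature: list[SpliceEvent],
    model: GeneModel,
    exon_seqs: dict[int, str],
    intron_seqs: dict[int, str],
    *,
    tail_first_exon: int = 12,
) -> IsoformAnnotation:
    """Translate a spliced isoform and deduce its protein consequences.

    Reports reading-frame integrity, premature-stop position, residues
    inserted by alternative splice-site usage, the ITIM count over the
    translated cytoplasmic tail, and whether a premature stop upstream of
    the transmembrane exon marks a candidate soluble isoform.
    """
    parts = apply_signature(model, exon_seqs, intron_seqs, signature)
    tags: list[float] = []
    for tag, seq in parts:
        tags.extend([tag] * len(seq))
    transcript = parts_to_seq(parts)
    # coding start: position of the start codon in the transcript
    start_exon = model.start_codon_exon
    pos = 0
    cds_start = None
    for tag, seq in parts:
        if tag == float(start_exon):
            cds_start = pos + model.exon(start_exon).coding_start
            break
        pos += len(seq)
    if cds_start is None:
        raise IncompatibleEventsError("start-codon exon absent from isoform")
    coding = transcript[cds_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = translate_cds(coding)
    stop_nt = cds_start + 3 * len(protein)  # first base of the stop codon
    # canonical stop position in this transcript (first base of stop codon)
    term = model.stop_codon_exon
    canonical_stop_nt = None
    pos = 0
    for tag, seq in parts:
        if tag == float(term):
            canonical_stop_nt = pos + model.exon(term).coding_prefix_len - 3
            break
        pos += len(seq)
    premature = canonical_stop_nt is None or stop_nt < canonical_stop_nt
    has_stop = 3 * len(protein) < len(coding)
    premature_stop = len(protein) if premature and has_stop else None
    cds_intact = has_stop and not premature
    # tail region: residues whose codon starts in/after the first tail exon
    tail_start = len(protein)
    for a in range(len(protein)):
        nt = cds_start + 3 * a
        if tags[nt] >= tail_first_exon - 0.5 and tags[nt] != float(
            int(tags[nt])
        ) or tags[nt] >= tail_first_exon:
            tail_start = a
            break
    itim_count = len(ITIM_RE.findall(protein[tail_start:]))
    inserted = None
    if cds_intact:
        canonical_parts = apply_signature(model, exon_seqs, intron_seqs, [])
        canonical_tx = parts_to_seq(canonical_parts)
        can_cds_start = sum(
            len(seq) for tag, seq in canonical_parts if tag < start_exon
        ) + model.exon(start_exon).coding_start
        can_coding = canonical_tx[can_cds_start:]
        can_prot = translate_cds(can_coding[: len(can_coding) - len(can_coding) % 3])
        inserted = _diff_insertion(can_prot, protein)
    tm_exon = next(
        (i for i, r in sorted(model.domain_map.items()) if r == "TM"), None
    )
    soluble = False
    if premature_stop is not None and tm_exon is not None:
        stop_tag = tags[stop_nt] if stop_nt < len(tags) else tags[-1]
        soluble = stop_tag < tm_exon
    return IsoformAnnotation(
        signature=list(signature),
        cds_intact=cds_intact,
        premature_stop=premature_stop,
        itim_count=itim_count,
        inserted_residues=inserted,
        soluble_candidate=soluble,
        protein=protein,
    )


# -- splice-site motifs ---------------------------------------------------

def detect_splice_motifs(genomic: str, model: GeneModel) -> dict:
    """Per-intron donor/acceptor dinucleotides plus cryptic-stop screening.

    Flags non-GT donors (e.g. the GT-to-GC mutation after exon 15 linked to
    exon-15 skipping) and checks for an in-frame stop codon beginning 3 nt
    downstream of the donor of the intron following the stem region, the
    signature of soluble-isoform-producing read-through transcripts.
    """
    introns: dict[int, dict] = {}
    idxs = model.exon_indices
    for i in idxs[:-1]:
        s, e = model.intron_span(i)
        seq = genomic[s:e]
        if len(seq) < 6:
            raise StructuralInconsistencyError(f"intron after exon {i} shorter than 6 nt")
        introns[i] = {
            "donor": seq[:2],
            "acceptor": seq[-2:],
            "canonical_donor": seq[:2] == "GT",
        }
    cryptic = False
    stem = model.stem_exons
    if stem:
        last_stem = max(stem)
        if last_stem != idxs[-1]:
            s, e = model.intron_span(last_stem)
            frame_ok = (
                model.coding_length_before(last_stem)
                + model.exon(last_stem).coding_prefix_len
            ) % 3 == 0
            cryptic = frame_ok and genomic[s + 3 : s + 6] in STOP_CODONS
    return {"introns": introns, "cryptic_stop_after_stem": cryptic}


# -- cross-animal shared-event filter -------------------------------------

def filter_shared_events(
    events: pd.DataFrame, *, min_animals: int = 2, min_species: int = 2
) -> pd.DataFrame:
    """Retain events (kind, exon, delta_bp) seen in >= ``min_animals``
    distinct animals AND >= ``min_species`` distinct species."""
    required = {"animal", "species", "kind", "exon", "delta_bp"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if events.empty:
        return events.iloc[0:0][["kind", "exon", "delta_bp"]].assign(
            n_animals=pd.Series(dtype=int), n_species=pd.Series(dtype=int)
        )
    g = events.groupby(["kind", "exon", "delta_bp"]).agg(
        n_animals=("animal", "nunique"), n_species=("species", "nunique")
    )
    keep = g[(g.n_animals >= min_animals) & (g.n_species >= min_species)]
    return keep.reset_index().sort_values(["exon", "kind", "delta_bp"]).reset_index(
        drop=True
    )


def signature_str(signature: list[SpliceEvent]) -> str:
    """Compact text form, e.g. ``"alt_3ss:10:+3;exon_skip:15:+0"``."""
    return ";".join(
        f"{ev.kind}:{ev.exon}:{ev.delta_bp:+d}" for ev in sorted(signature)
    )


def parse_signature(text: str) -> list[SpliceEvent]:
    if not text:
        return []
    out = []
    for token in text.split(";"):
        kind, exon, delta = token.split(":")
        out.append(SpliceEvent(int(exon), kind, int(delta)))
    return out


def events_per_exon(catalog: pd.DataFrame) -> pd.Series:
    """Stacked per-exon event counts (Fig-7-style summary)."""
    if catalog.empty:
        return pd.Series(dtype=int)
    return catalog.groupby("exon").size().sort_index()
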