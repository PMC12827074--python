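"""Splice-event classification, protein consequences, and the shared-event
filter, exercised over the documented isoform catalog."""

import itertools

import pandas as pd
import pytest

from lilrseq.gene_model import StructuralInconsistencyError, build_canonical_model
from lilrseq.splice import (
    IncompatibleEventsError,
    NoDerivationError,
    SpliceEvent,
    align_transcript,
    annotate_protein,
    classify_events,
    detect_splice_motifs,
    filter_shared_events,
    parse_signature,
    signature_str,
    signature_transcript_length,
)
from lilrseq.synthetic import canonical_fixture, simulate_isoform

# the documented isoform catalog plus extra event types seen in the data
B1_EVENTS = [
    SpliceEvent(10, "alt_3ss", 3),
    SpliceEvent(15, "alt_3ss", 3),
    SpliceEvent(15, "exon_skip"),
    SpliceEvent(15, "intron_retention", 30),
    SpliceEvent(10, "micro_insertion", 1),
    SpliceEvent(10, "micro_insertion", 2),
    SpliceEvent(14, "alt_5ss", -6),
]
B2_EVENTS = [
    SpliceEvent(9, "exon_skip"),
    SpliceEvent(10, "exon_skip"),
    SpliceEvent(10, "alt_3ss", 3),
    SpliceEvent(15, "alt_3ss", 3),
    SpliceEvent(10, "micro_insertion", 2),
    SpliceEvent(15, "intron_retention", 30),
]


def _signatures(events):
    yield []
    for ev in events:
        yield [ev]
    for a, b in itertools.combinations(events, 2):
        yield [a, b]


def _compatible(sig):
    skips = {e.exon for e in sig if e.kind == "exon_skip"}
    sides = [
        (e.exon, "a" if e.kind in ("alt_3ss", "micro_insertion") else
         "d" if e.kind in ("alt_5ss", "intron_retention") else "s")
        for e in sig
    ]
    if any(e.kind != "exon_skip" and e.exon in skips for e in sig):
        return False
    return len(sides) == len(set(sides))


class TestRoundTrip:
    @pytest.mark.parametrize("gene,events", [("LILRB1", B1_EVENTS),
                                             ("LILRB2", B2_EVENTS)])
    def test_simulate_align_classify_recovers_signature(self, gene, events,
                                                        lilrb1, lilrb2):
        rec = lilrb1 if gene == "LILRB1" else lilrb2
        n_checked = 0
        for sig in _signatures(events):
            if not _compatible(sig):
                with pytest.raises(IncompatibleEventsError):
                    simulate_isoform(rec, sig)
                continue
            tx = simulate_isoform(rec, sig)
            assert len(tx) == signature_transcript_length(rec.model, sig)
            blocks = align_transcript(tx, rec.seq, rec.model)
            assert classify_events(blocks, rec.model) == sorted(sig)
            n_checked += 1
        assert n_checked >= 18

    def test_full_intron_retention_fuses_exons(self, lilrb1):
        intron_len = len(lilrb1.intron_seqs[15])
        sig = [SpliceEvent(15, "intron_retention", intron_len)]
        tx = simulate_isoform(lilrb1, sig)
        blocks = align_transcript(tx, lilrb1.seq, lilrb1.model)
        assert classify_events(blocks, lilrb1.model) == sig

    def test_signature_text_round_trip(self):
        sig = [SpliceEvent(10, "alt_3ss", 3), SpliceEvent(15, "exon_skip")]
        assert parse_signature(signature_str(sig)) == sorted(sig)


class TestAlignment:
    def test_canonical_blocks_are_the_mature_exons(self, lilrb1):
        tx = simulate_isoform(lilrb1, [])
        blocks = align_transcript(tx, lilrb1.seq, lilrb1.model)
        spans = [(b.g_start, b.g_end) for b in blocks]
        expected = [(e.start, e.end) for e in lilrb1.model.mature_exons()]
        assert spans == expected

    def test_foreign_transcript_raises_no_derivation(self, lilrb1):
        tx = simulate_isoform(lilrb1, [])
        pos = 1000
        mutated = tx[:pos] + ("A" if tx[pos] != "A" else "C") + tx[pos + 1 :]
        with pytest.raises(NoDerivationError):
            align_transcript(mutated, lilrb1.seq, lilrb1.model)

    def test_mismatch_budget_bridges_sequencing_errors(self, lilrb1):
        tx = simulate_isoform(lilrb1, [SpliceEvent(15, "exon_skip")])
        pos = 600  # mid-exon, away from junctions
        mutated = tx[:pos] + ("A" if tx[pos] != "A" else "C") + tx[pos + 1 :]
        blocks = align_transcript(mutated, lilrb1.seq, lilrb1.model,
                                  max_mismatches=1)
        assert classify_events(blocks, lilrb1.model) == [
            SpliceEvent(15, "exon_skip")
        ]


class TestProteinConsequences:
    def test_exon10_plus3_inserts_alanine(self, lilrb1):
        ann = annotate_protein([SpliceEvent(10, "alt_3ss", 3)], lilrb1.model,
                               lilrb1.exon_seqs, lilrb1.intron_seqs)
        assert ann.inserted_residues == "A"
        assert ann.cds_intact and ann.premature_stop is None

    def test_exon15_plus3_inserts_glutamine(self, lilrb1):
        ann = annotate_protein([SpliceEvent(15, "alt_3ss", 3)], lilrb1.model,
                               lilrb1.exon_seqs, lilrb1.intron_seqs)
        assert ann.inserted_residues == "Q"
        assert ann.cds_intact

    def test_exon15_skip_drops_one_itim(self, lilrb1):
        ann = annotate_protein([SpliceEvent(15, "exon_skip")], lilrb1.model,
                               lilrb1.exon_seqs, lilrb1.intron_seqs)
        assert ann.itim_count == 3
        assert ann.cds_intact  # exon 15 is phase-preserving

    @pytest.mark.parametrize("delta", [1, 2])
    def test_micro_insertion_causes_premature_stop_before_tm(self, lilrb1, delta):
        ann = annotate_protein([SpliceEvent(10, "micro_insertion", delta)],
                               lilrb1.model, lilrb1.exon_seqs, lilrb1.intron_seqs)
        assert ann.premature_stop is not None
        assert not ann.cds_intact
        assert ann.soluble_candidate

    def test_itim_count_never_increases_when_exons_removed(self, lilrb1):
        base = annotate_protein([], lilrb1.model, lilrb1.exon_seqs,
                                lilrb1.intron_seqs).itim_count
        for exon in (13, 14, 15):
            ann = annotate_protein([SpliceEvent(exon, "exon_skip")],
                                   lilrb1.model, lilrb1.exon_seqs,
                                   lilrb1.intron_seqs)
            assert ann.itim_count == base - 1

    def test_lilrb2_exon9_skip_shortens_stem_in_frame(self, lilrb2):
        ann = annotate_protein([SpliceEvent(9, "exon_skip")], lilrb2.model,
                               lilrb2.exon_seqs, lilrb2.intron_seqs)
        assert ann.cds_intact
        assert len(ann.protein) == 654 - 15  # 45-bp exon 9


class TestSpliceMotifs:
    def test_canonical_donors_and_acceptors(self, lilrb1):
        out = detect_splice_motifs(lilrb1.seq, lilrb1.model)
        assert all(v["donor"] == "GT" for v in out["introns"].values())
        assert all(v["acceptor"] == "AG" for v in out["introns"].values())
        assert not out["cryptic_stop_after_stem"]

    def test_gc_donor_after_exon15_flagged(self):
        rec = canonical_fixture("LILRB1", gc_donor_after_exon15=True)
        out = detect_splice_motifs(rec.seq, rec.model)
        assert out["introns"][15]["donor"] == "GC"
        assert not out["introns"][15]["canonical_donor"]
        assert all(v["canonical_donor"] for i, v in out["introns"].items() if i != 15)

    def test_cryptic_stop_three_nt_into_stem_intron(self):
        rec = canonical_fixture("LILRB1", cryptic_stop_after_stem=True)
        out = detect_splice_motifs(rec.seq, rec.model)
        assert out["cryptic_stop_after_stem"]
        # direct translation of the read-through transcript confirms the stop
        ann = annotate_protein(
            [SpliceEvent(10, "intron_retention", 12)], rec.model,
            rec.exon_seqs, rec.intron_seqs,
        )
        assert ann.premature_stop is not None
        assert ann.soluble_candidate

    def test_short_intron_rejected(self):
        m = build_canonical_model("toy", {1: 9, 2: 6}, {1: 4},
                                  first_mrna_exon=1, stop_codon_offset=6,
                                  domain_map={1: "stem"})
        with pytest.raises(StructuralInconsistencyError):
            detect_splice_motifs("ATGGCAGCAGTAGGCATAA", m)


class TestSharedEventFilter:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["animal", "species", "kind", "exon", "delta_bp"]
        )

    def test_enumeration_oracle(self):
        rows = [
            # 3 animals, 1 species -> excluded
            ("a1", "Mamu", "exon_skip", 15, 0),
            ("a2", "Mamu", "exon_skip", 15, 0),
            ("a3", "Mamu", "exon_skip", 15, 0),
            # 1 animal each of 2 species -> included
            ("a1", "Mamu", "alt_3ss", 10, 3),
            ("b1", "Mafa", "alt_3ss", 10, 3),
            # 1 animal, 1 species -> excluded
            ("c1", "Paha", "intron_retention", 15, 30),
        ]
        out = filter_shared_events(self._table(rows))
        assert len(out) == 1
        assert tuple(out.iloc[0][["kind", "exon", "delta_bp"]]) == (
            "alt_3ss", 10, 3
        )
        # brute-force oracle over the same table
        df = self._table(rows)
        expect = {
            key
            for key, grp in df.groupby(["kind", "exon", "delta_bp"])
            if grp.animal.nunique() >= 2 and grp.species.nunique() >= 2
        }
        got = set(map(tuple, out[["kind", "exon", "delta_bp"]].to_numpy()))
        assert got == expect

    def test_empty_table_gives_empty_catalog(self):
        out = filter_shared_events(self._table([]))
        assert out.empty
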