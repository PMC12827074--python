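"""Exact-match calling, contig clustering, confirmation, and closure."""

from collections import Counter

import pytest

from lilrseq import allele_discovery as ad
from lilrseq.read_processing import CcsRead
from lilrseq.records import AlleleRecord, ReferenceLibrary
from lilrseq.splice import parse_signature
from lilrseq.synthetic import simulate_isoform


def _lib(*seqs, gene="LILRB1"):
    return ReferenceLibrary(
        [
            AlleleRecord(name=f"ref{i}", seq=s, gene=gene, kind="transcript")
            for i, s in enumerate(seqs, 1)
        ]
    )


@pytest.fixture(scope="module")
def ref_tx(lilrb1):
    return simulate_isoform(lilrb1, [])


class TestExactMatch:
    def test_exact_substring_assigned(self, ref_tx):
        read = CcsRead("r", ref_tx[100:700], 0.999, sample="S")
        asn, un = ad.match_to_reference([read], _lib(ref_tx))
        assert len(asn) == 1 and not un

    def test_single_mismatch_rejected(self, ref_tx):
        seq = ref_tx[100:700]
        mutated = seq[:300] + ("A" if seq[300] != "A" else "C") + seq[301:]
        asn, un = ad.match_to_reference([CcsRead("r", mutated, 0.999)], _lib(ref_tx))
        assert not asn and len(un) == 1

    def test_single_ambiguous_base_tolerated(self, ref_tx):
        seq = ref_tx[100:700]
        asn, _ = ad.match_to_reference(
            [CcsRead("r", seq[:300] + "N" + seq[301:], 0.999)], _lib(ref_tx)
        )
        assert len(asn) == 1
        _, un = ad.match_to_reference(
            [CcsRead("r", "NN" + seq[2:], 0.999)], _lib(ref_tx)
        )
        assert len(un) == 1

    def test_short_read_below_min_overlap_unassigned(self, ref_tx):
        asn, un = ad.match_to_reference([CcsRead("r", ref_tx[:399], 0.999)],
                                        _lib(ref_tx))
        assert not asn and len(un) == 1

    def test_multi_reference_hits_flagged_ambiguous(self, ref_tx):
        other = ref_tx[:-1] + ("A" if ref_tx[-1] != "A" else "C")
        lib = _lib(ref_tx, other)
        read = CcsRead("r", ref_tx[0:500], 0.999)  # shared prefix of both
        asn, _ = ad.match_to_reference([read], lib)
        assert len(asn) == 2 and all(a.ambiguous for a in asn)

    def test_empty_library_rejected(self, ref_tx):
        with pytest.raises(ValueError):
            ad.match_to_reference([], ReferenceLibrary())

    def test_assigned_reads_are_true_substrings(self, small_demuxed):
        """Exact-match soundness at error 0 against a full truth library."""
        cfg, truth, per_sample, _ = small_demuxed
        lib = ReferenceLibrary(
            [
                AlleleRecord(name=f"{a}|{s or 'C'}", seq=seq, gene=cfg.gene,
                             kind="transcript")
                for (a, s), seq in truth.all_transcripts().items()
            ]
        )
        seq_of = {rec.name: rec.seq for rec in lib}
        n = 0
        for sample, reads in per_sample.items():
            asn, un = ad.match_to_reference(reads, lib)
            assert not un
            by_id = {r.id: r for r in reads}
            for a in asn:
                assert by_id[a.read_id].seq in seq_of[a.allele]
            n += len(asn)
        assert n > 0


class TestClustering:
    def test_five_identical_reads_one_candidate(self, ref_tx):
        reads = [CcsRead(f"r{i}", ref_tx, 0.999, sample="S") for i in range(5)]
        out = ad.cluster_unassigned(reads)
        assert len(out) == 1 and out[0].support == 5
        assert out[0].consensus == ref_tx

    def test_two_reads_below_cutoff_discarded(self, ref_tx):
        reads = [CcsRead(f"r{i}", ref_tx, 0.999, sample="S") for i in range(2)]
        assert ad.cluster_unassigned(reads) == []

    def test_consensus_corrects_single_errors(self, ref_tx):
        reads = []
        for i, pos in enumerate((100, 900, 1500)):
            alt = "A" if ref_tx[pos] != "A" else "G"
            reads.append(
                CcsRead(f"r{i}", ref_tx[:pos] + alt + ref_tx[pos + 1 :], 0.999,
                        sample="S")
            )
        out = ad.cluster_unassigned(reads)
        assert len(out) == 1
        # independent per-column majority oracle
        oracle = "".join(
            Counter(col).most_common(1)[0][0] for col in zip(*(r.seq for r in reads))
        )
        assert out[0].consensus == oracle == ref_tx

    def test_distinct_alleles_not_merged(self, ref_tx):
        other = list(ref_tx)
        for pos in range(50, 50 + 30 * 25, 30):  # ~1.1% divergence
            other[pos] = "A" if other[pos] != "A" else "G"
        other = "".join(other)
        reads = [CcsRead(f"a{i}", ref_tx, 0.999, sample="S") for i in range(3)]
        reads += [CcsRead(f"b{i}", other, 0.999, sample="S") for i in range(3)]
        out = ad.cluster_unassigned(reads)
        assert len(out) == 2
        assert {c.consensus for c in out} == {ref_tx, other}


class TestConfirmation:
    def _cand(self, seq, sample, runs):
        return ad.Candidate(seq, 5, sample, frozenset(runs))

    def test_two_individuals_confirm(self):
        cands = [self._cand("ACGT" * 200, "A", {"run1"}),
                 self._cand("ACGT" * 200, "B", {"run1"})]
        assert len(ad.confirm_novel(cands)) == 1

    def test_one_individual_one_run_stays_candidate(self):
        assert ad.confirm_novel([self._cand("ACGT" * 200, "A", {"run1"})]) == []

    def test_one_individual_two_runs_confirms(self):
        assert len(ad.confirm_novel(
            [self._cand("ACGT" * 200, "A", {"run1", "run2"})]
        )) == 1


class TestDiscoveryLoop:
    def test_closure_and_no_false_novels_at_error_zero(self, small_demuxed):
        cfg, truth, per_sample, _ = small_demuxed
        run_of = dict(zip(truth.reads.read_id, truth.reads.run))
        seed = ReferenceLibrary(
            [AlleleRecord(name="seed", seq=truth.transcript(
                truth.alleles[0].name, ""), gene=cfg.gene, kind="transcript")]
        )
        res = ad.discover_alleles(per_sample, seed, run_of=run_of)
        truth_tx = set(truth.all_transcripts().values())
        assert all(rec.seq in truth_tx for rec in res.confirmed)
        # fixed point: a second pass on the same data confirms nothing new
        res2 = ad.discover_alleles(per_sample, res.library, run_of=run_of)
        assert res2.confirmed == []
        assert res2.iterations == 1

    def test_full_truth_library_confirms_no_novels(self, small_demuxed):
        cfg, truth, per_sample, _ = small_demuxed
        lib = ReferenceLibrary(
            [AlleleRecord(name=f"{a}|{s or 'C'}", seq=seq, gene=cfg.gene,
                          kind="transcript")
             for (a, s), seq in truth.all_transcripts().items()]
        )
        res = ad.discover_alleles(per_sample, lib)
        assert res.confirmed == []
        assert not res.unassigned

    def test_library_growth_is_monotone_in_assignments(self, small_demuxed):
        cfg, truth, per_sample, _ = small_demuxed
        reads = [r for lst in per_sample.values() for r in lst]
        small = ReferenceLibrary(
            [AlleleRecord(name="a", seq=truth.transcript(
                truth.alleles[0].name, ""), gene=cfg.gene, kind="transcript")]
        )
        asn_small, _ = ad.match_to_reference(reads, small)
        full = ReferenceLibrary(
            [AlleleRecord(name=f"{a}|{s or 'C'}", seq=seq, gene=cfg.gene,
                          kind="transcript")
             for (a, s), seq in truth.all_transcripts().items()]
        )
        asn_full, _ = ad.match_to_reference(reads, full)
        assert len({a.read_id for a in asn_full}) >= len(
            {a.read_id for a in asn_small}
        )


class TestReconcile:
    def test_canonical_and_spliced_transcripts_link(self, lilrb1):
        canonical = simulate_isoform(lilrb1, [])
        skipped = simulate_isoform(lilrb1, parse_signature("exon_skip:15:+0"))
        txs = [
            AlleleRecord(name="t_canon", seq=canonical, kind="transcript"),
            AlleleRecord(name="t_skip", seq=skipped, kind="transcript"),
            AlleleRecord(name="t_orphan", seq="ACGT" * 200, kind="transcript"),
        ]
        df = ad.reconcile_cdna_gdna(txs, [lilrb1]).set_index("transcript")
        assert df.loc["t_canon", "status"] == "linked"
        assert df.loc["t_canon", "signature"] == ""
        assert df.loc["t_skip", "signature"] == "exon_skip:15:+0"
        assert df.loc["t_orphan", "status"] == "transcript-only"

    def test_transcript_derivable_from_two_genomics_is_ambiguous(self, lilrb1):
        canonical = simulate_isoform(lilrb1, [])
        twin = AlleleRecord(
            name="twin", seq=lilrb1.seq, gene=lilrb1.gene, model=lilrb1.model,
            exon_seqs=lilrb1.exon_seqs, intron_seqs=lilrb1.intron_seqs,
        )
        df = ad.reconcile_cdna_gdna(
            [AlleleRecord(name="t", seq=canonical, kind="transcript")],
            [lilrb1, twin],
        )
        assert df.iloc[0]["status"] == "ambiguous"
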