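"""CCS read pre-processing: quality filtering and barcode demultiplexing.

Consensus reads carry a read-quality value (``rq``, predicted consensus
accuracy in [0, 1]); the study contract retains reads with rq >= 0.99.
Demultiplexing assigns a read to the unique sample whose 16-bp forward and
reverse barcodes both match within ``max_mismatch`` after trying both
orientations; ambiguous and non-matching reads stay unassigned and barcodes
are trimmed from assigned reads.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_RQ_RE = re.compile(r"rq=([0-9.]+)")


@dataclass
class CcsRead:
    id: str
    seq: str
    rq: float | None = None
    barcode_fwd: str | None = None
    barcode_rev: str | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.rq is not None and not 0.0 <= self.rq <= 1.0:
            raise ValueError(f"read {self.id}: rq {self.rq} outside [0, 1]")


def read_fastq(path) -> list[CcsRead]:
    """Parse FASTQ with ``rq=`` tags in the description line."""
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        m = _RQ_RE.search(rec.description)
        reads.append(CcsRead(rec.id, str(rec.seq), float(m.group(1)) if m else None))
    return reads


def filter_by_quality(
    reads, threshold: float = 0.99, *, on_missing: str = "fail"
):
    """Retain reads with rq >= threshold, preserving order.

    Reads lacking an rq value are rejected (``on_missing="reject"``) or raise
    (default ``"fail"``).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept, dropped = [], 0
    for read in reads:
        if read.rq is None:
            if on_missing == "fail":
                raise ValueError(f"read {read.id} lacks an rq tag")
            dropped += 1
            continue
        if read.rq >= threshold:
            kept.append(read)
        else:
            dropped += 1
    log.info("quality filter: %d kept, %d removed (threshold %.3f)",
             len(kept), dropped, threshold)
    return kept


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def check_barcode_manifest(manifest: pd.DataFrame, max_mismatch: int) -> None:
    """Barcode pairs must be mutually separated by Hamming distance
    > 2 * max_mismatch (jointly over both tags)."""
    pairs = list(zip(manifest["fwd_barcode"], manifest["rev_barcode"]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("barcode manifest contains non-unique barcode pairs")
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            d = _hamming(pairs[i][0], pairs[j][0]) + _hamming(pairs[i][1], pairs[j][1])
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"barcode pairs for samples {manifest['sample'].iloc[i]!r} and "
                    f"{manifest['sample'].iloc[j]!r} are too similar (joint "
                    f"distance {d} <= {2 * max_mismatch})"
                )


def demultiplex(
    reads: list[CcsRead],
    manifest: pd.DataFrame,
    max_mismatch: int = 1,
) -> tuple[dict[str, list[CcsRead]], list[CcsRead]]:
    """Assign reads to samples by their terminal barcode pair.

    Both orientations are scored; the better joint barcode score wins, ties
    go unassigned. Assigned reads are orientation-normalized and trimmed.
    Returns ``(per_sample, unassigned)``; the two partitions the input.
    """
    check_barcode_manifest(manifest, max_mismatch)
    bl = len(manifest["fwd_barcode"].iloc[0])
    expected = [
        (row.sample, row.fwd_barcode, str(Seq(row.rev_barcode).reverse_complement()))
        for row in manifest.itertuples(index=False)
    ]
    per_sample: dict[str, list[CcsRead]] = {s: [] for s, _, _ in expected}
    unassigned: list[CcsRead] = []
    for read in reads:
        if len(read.seq) < 2 * bl + 1:
            unassigned.append(read)
            continue
        candidates = []  # (score, sample, oriented_seq)
        for seq in (read.seq, str(Seq(read.seq).reverse_complement())):
            head, tail = seq[:bl], seq[-bl:]
            for sample, fwd, rev_rc in expected:
                d_f, d_r = _hamming(head, fwd), _hamming(tail, rev_rc)
                if d_f <= max_mismatch and d_r <= max_mismatch:
                    candidates.append((d_f + d_r, sample, seq))
        if not candidates:
            unassigned.append(read)
            continue
        candidates.sort(key=lambda c: c[0])
        best = candidates[0]
        ties = [c for c in candidates if c[0] == best[0]]
        if len({c[1] for c in ties}) > 1:
            unassigned.append(read)
            continue
        seq = best[2]
        per_sample[best[1]].append(
            CcsRead(
                read.id,
                seq[bl:-bl],
                read.rq,
                barcode_fwd=seq[:bl],
                barcode_rev=str(Seq(seq[-bl:]).reverse_complement()),
                sample=best[1],
            )
        )
    for sample, lst in per_sample.items():
        log.info("demultiplex: %s -> %d reads", sample, len(lst))
    log.info("demultiplex: %d unassigned", len(unassigned))
    return per_sample, unassigned
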