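"""Shared record types: alleles and reference libraries."""

from __future__ import annotations

from dataclasses import dataclass, field

from .gene_model import GeneModel, assemble_genomic


@dataclass
class AlleleRecord:
    """A named genomic or transcript sequence with provenance.

    ``exon_seqs``/``intron_seqs``/``model`` are populated for genomic alleles
    whose exon architecture is known (all simulated alleles); transcript-only
    records carry just the sequence.
    """

    name: str
    seq: str
    gene: str = "LILRB1"
    species: str = "Mamu"
    source: str = "published"  # published | this-run | simulated
    kind: str = "genomic"  # genomic | transcript
    lineage: str | None = None
    model: GeneModel | None = None
    exon_seqs: dict[int, str] = field(default_factory=dict)
    intron_seqs: dict[int, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def rebuild_seq(self) -> None:
        if self.model is not None and self.exon_seqs:
            self.seq = assemble_genomic(self.model, self.exon_seqs, self.intron_seqs)


class ReferenceLibrary:
    """Versioned per-gene allele library; names and sequences unique."""

    def __init__(
        self,
        entries: list[AlleleRecord] | None = None,
        *,
        strict_seqs: bool = True,
    ) -> None:
        self.entries: list[AlleleRecord] = []
        self.version = 0
        self.strict_seqs = strict_seqs
        self._names: set[str] = set()
        self._seqs: set[tuple[str, str]] = set()
        for rec in entries or []:
            self._insert(rec)

    def _insert(self, rec: AlleleRecord) -> None:
        if rec.name in self._names:
            raise ValueError(f"duplicate allele name {rec.name!r}")
        key = (rec.gene, rec.seq)
        if key in self._seqs:
            if self.strict_seqs:
                raise ValueError(f"duplicate sequence for {rec.gene} ({rec.name})")
            import logging

            logging.getLogger(__name__).warning(
                "duplicate sequence under a second name: %s", rec.name
            )
        self.entries.append(rec)
        self._names.add(rec.name)
        self._seqs.add(key)

    def add(self, records: list[AlleleRecord]) -> None:
        """Append confirmed records and bump the library version."""
        for rec in records:
            self._insert(rec)
        self.version += 1

    def contains_seq(self, gene: str, seq: str) -> bool:
        return (gene, seq) in self._seqs

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)
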