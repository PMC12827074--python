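"""Allele nomenclature: ``Mamu-LILRB1*001:01:01:01`` grammar.

The four-letter taxon prefix combines the first two letters of the genus
with the first two of the species epithet (Macaca mulatta -> Mamu, Papio
hamadryas -> Paha). After the gene name and asterisk, the first (3-digit)
field is the lineage — a group of alleles clustering together in
phylogenetic analyses — and the optional 2-digit fields two to four denote
allelic (nonsynonymous) variation, synonymous coding changes, and
non-coding differences. The suffix ``Sp`` marks an allele described from a
splice-variant transcript.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .gene_model import GeneModel, extract_cds, translate_cds

NAME_RE = re.compile(
    r"^(?P<prefix>[A-Z][a-z]{3})-(?P<gene>[A-Za-z0-9]+)"
    r"\*(?P<lineage>\d{3})"
    r"(?::(?P<allele>\d{2}))?"
    r"(?::(?P<synonymous>\d{2}))?"
    r"(?::(?P<noncoding>\d{2}))?"
    r"(?P<sp>Sp)?$"
)


class NameParseError(ValueError):
    def __init__(self, text: str, position: int, message: str) -> None:
        super().__init__(f"{message} in {text!r} at position {position}")
        self.position = position


@dataclass(frozen=True)
class AlleleName:
    prefix: str  # 4-letter taxon code, e.g. Mamu
    gene: str
    lineage: int
    allele: int | None = None
    synonymous: int | None = None
    noncoding: int | None = None
    sp_suffix: bool = False

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z][a-z]{3}", self.prefix):
            raise ValueError(f"malformed taxon prefix {self.prefix!r}")
        if not 0 < self.lineage < 1000:
            raise ValueError("lineage field must be a positive 3-digit number")
        fields = (self.allele, self.synonymous, self.noncoding)
        seen_none = False
        for f in fields:
            if f is None:
                seen_none = True
            elif seen_none:
                raise ValueError("name fields must be contiguous")
            elif not 0 < f < 100:
                raise ValueError("fields 2-4 must be positive 2-digit numbers")


def species_prefix(genus: str, species: str) -> str:
    """First two letters of the genus + first two of the species epithet."""
    if len(genus) < 2 or len(species) < 2:
        raise ValueError("genus and species need at least two letters")
    return genus[:2].capitalize() + species[:2].lower()


def format_name(name: AlleleName) -> str:
    out = f"{name.prefix}-{name.gene}*{name.lineage:03d}"
    for f in (name.allele, name.synonymous, name.noncoding):
        if f is None:
            break
        out += f":{f:02d}"
    if name.sp_suffix:
        out += "Sp"
    return out


def parse_name(text: str) -> AlleleName:
    m = NAME_RE.match(text)
    if not m:
        # locate the first offending position for the error message
        probe = re.compile(r"^[A-Z][a-z]{3}-")
        pos = 0 if not probe.match(text) else text.find("*")
        raise NameParseError(text, max(pos, 0), "malformed allele name")
    g = m.groupdict()
    return AlleleName(
        prefix=g["prefix"],
        gene=g["gene"],
        lineage=int(g["lineage"]),
        allele=int(g["allele"]) if g["allele"] else None,
        synonymous=int(g["synonymous"]) if g["synonymous"] else None,
        noncoding=int(g["noncoding"]) if g["noncoding"] else None,
        sp_suffix=bool(g["sp"]),
    )


def _classify_difference(
    ref_seq: str, new_seq: str, ref_model: GeneModel, new_model: GeneModel
) -> str:
    """nonsynonymous | synonymous | noncoding | identical, comparing a new
    allele to its lineage reference."""
    ref_cds = extract_cds(ref_model, ref_seq)
    new_cds = extract_cds(new_model, new_seq)
    if translate_cds(ref_cds) != translate_cds(new_cds):
        return "nonsynonymous"
    if ref_cds != new_cds:
        return "synonymous"
    if ref_seq != new_seq:
        return "noncoding"
    return "identical"


def assign_allele_names(
    records,
    lineage_of: dict[str, str],
    *,
    prefix: str,
    gene: str,
    sp_alleles: set[str] | None = None,
) -> dict[str, AlleleName]:
    """Names for a set of genomic alleles under a lineage assignment.

    Within each lineage the first allele becomes the reference
    (``*LLL:01:01:01``); every further allele is classified against it:
    any nonsynonymous difference opens a new field-2 value, a synonymous
    coding difference a new field-3 value, intronic/UTR-only differences a
    new field-4 value.
    """
    sp_alleles = sp_alleles or set()
    by_lineage: dict[str, list] = {}
    for rec in records:
        by_lineage.setdefault(lineage_of[rec.name], []).append(rec)
    out: dict[str, AlleleName] = {}
    for lid in sorted(by_lineage):
        members = by_lineage[lid]
        ref = members[0]
        counters = {"nonsynonymous": 1, "synonymous": 1, "noncoding": 1}
        out[ref.name] = AlleleName(
            prefix, gene, int(lid), 1, 1, 1, sp_suffix=ref.name in sp_alleles
        )
        for rec in members[1:]:
            kind = _classify_difference(ref.seq, rec.seq, ref.model, rec.model)
            a = s = n = 1
            if kind in ("nonsynonymous", "identical"):
                counters["nonsynonymous"] += 1
                a = counters["nonsynonymous"]
            elif kind == "synonymous":
                counters["synonymous"] += 1
                s = counters["synonymous"]
            else:
                counters["noncoding"] += 1
                n = counters["noncoding"]
            out[rec.name] = AlleleName(
                prefix, gene, int(lid), a, s, n, sp_suffix=rec.name in sp_alleles
            )
    return out
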