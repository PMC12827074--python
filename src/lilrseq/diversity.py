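"""Allelic diversity summaries.

Per-position amino-acid variability (count of unique residues per aligned
column), per-exon synonymous/nonsynonymous mutation counts normalized to
exon coding length, groups of alleles sharing identical deduced peptides
over chosen domains (e.g. D1, D2, D1-D2), and position-wise residue
frequency tables suitable for stacked-bar rendering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gene_model import GeneModel, translate_cds


def _as_rows(alignment) -> list[str]:
    if isinstance(alignment, dict):
        rows = list(alignment.values())
    else:
        rows = [str(s) for s in alignment]
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows must have equal length")
    return rows


def variability_profile(aa_alignment, *, count_gaps: bool = False) -> np.ndarray:
    """Number of unique amino acids per aligned position (gaps excluded by
    default); an all-conserved column scores 1."""
    rows = _as_rows(aa_alignment)
    ncol = len(rows[0])
    out = np.zeros(ncol, dtype=int)
    for i in range(ncol):
        residues = {r[i] for r in rows}
        if not count_gaps:
            residues -= {"-", ".", "X"}
        out[i] = max(len(residues), 1)
    return out


def exon_of_coding_position(model: GeneModel) -> list[int]:
    """Exon index for every coding position (pre-computed lookup)."""
    out = []
    for ex in model.mature_exons():
        out.extend([ex.index] * ex.coding_prefix_len)
    return out


def exon_mutation_density(cds_alignment, model: GeneModel) -> pd.DataFrame:
    """Per-exon synonymous/nonsynonymous variant counts, length-normalized.

    For every variable codon, each distinct observed alternative codon is
    compared to the column's consensus (majority) codon and classified as
    synonymous (same residue) or nonsynonymous; multi-position changes in
    one codon count as a single event classified by the net residue effect.
    Counts are divided by the exon's coding length.
    """
    rows = _as_rows(cds_alignment)
    if len(rows[0]) % 3:
        raise ValueError("CDS alignment length must be a multiple of 3")
    exon_map = exon_of_coding_position(model)
    if len(exon_map) != len(rows[0]):
        raise ValueError("alignment does not match the model's coding length")
    counts: dict[int, dict[str, float]] = {
        ex.index: {"S": 0, "NS": 0} for ex in model.mature_exons()
    }
    for c in range(0, len(rows[0]), 3):
        codons = [r[c : c + 3] for r in rows]
        clean = [cd for cd in codons if set(cd) <= set("ACGT")]
        if not clean:
            continue
        consensus = pd.Series(clean).mode().iloc[0]
        ref_aa = translate_cds(consensus) or "*"
        for alt in sorted(set(clean) - {consensus}):
            kind = "S" if (translate_cds(alt) or "*") == ref_aa else "NS"
            counts[exon_map[c]][kind] += 1
    out = []
    for ex in model.mature_exons():
        ln = ex.coding_prefix_len
        if ln == 0:
            continue
        s, ns = counts[ex.index]["S"], counts[ex.index]["NS"]
        out.append(
            {
                "exon": ex.index, "coding_length": ln, "S": int(s), "NS": int(ns),
                "S_per_bp": s / ln, "NS_per_bp": ns / ln,
            }
        )
    return pd.DataFrame(out)


def region_peptide(allele, model: GeneModel, region_exons: tuple[int, ...]) -> str:
    """Deduced peptide over the coding portions of the given exons."""
    parts = []
    for i in region_exons:
        s, e = model.coding_span(i)
        parts.append(allele.seq[s:e])
    seq = "".join(parts)
    phase = model.coding_length_before(region_exons[0]) % 3
    if phase:  # trim to whole codons within the region
        seq = seq[3 - phase :]
    seq = seq[: len(seq) - len(seq) % 3]
    return translate_cds(seq)


def domain_identity_groups(
    alleles,
    region_sets: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Partition alleles by exact peptide identity over each region set.

    Default regions mirror the domain-sharing analysis: D1 (exon 5),
    D2 (exon 6), and the combined D1-D2 (exons 5-6). Groups spanning more
    than one species are flagged ``cross_species``.
    """
    region_sets = region_sets or {"D1": (5,), "D2": (6,), "D1-D2": (5, 6)}
    rows = []
    for region, exons in region_sets.items():
        groups: dict[str, list] = {}
        for rec in alleles:
            if rec.model is None:
                continue
            try:
                pep = region_peptide(rec, rec.model, exons)
            except Exception:
                continue  # untranslatable allele: excluded
            groups.setdefault(pep, []).append(rec)
        for gi, (pep, members) in enumerate(
            sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])), start=1
        ):
            rows.append(
                {
                    "region": region,
                    "group": gi,
                    "n_alleles": len(members),
                    "alleles": ";".join(m.name for m in members),
                    "cross_species": len({m.species for m in members}) > 1,
                    "peptide": pep,
                }
            )
    return pd.DataFrame(rows)


def plot_variability(profile, path) -> None:
    """Per-position bar chart of unique-residue counts (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2.5))
    ax.bar(range(1, len(profile) + 1), profile, width=1.0, color="#3b6ea5")
    ax.set_xlabel("alignment position (aa)")
    ax.set_ylabel("unique AA")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_residue_frequencies(table: pd.DataFrame, path) -> None:
    """Stacked bar plot of residue frequencies at the table's positions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(index="position", columns="residue",
                              values="frequency", fill_value=0.0)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(pivot)), 3))
    bottom = np.zeros(len(pivot))
    for res in pivot.columns:
        ax.bar([str(p) for p in pivot.index], pivot[res], bottom=bottom,
               label=res)
        bottom += pivot[res].to_numpy()
    ax.set_ylabel("frequency")
    ax.set_xlabel("position")
    ax.legend(fontsize=6, ncol=2, frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def residue_frequency_table(
    aa_alignment, positions: list[int] | None = None
) -> tuple[pd.DataFrame, list[int]]:
    """Residue counts and frequencies per (1-based) position.

    Returns the long-format table (position, residue, count, frequency)
    and the list of positions invariant across the whole alignment.
    """
    rows = _as_rows(aa_alignment)
    ncol = len(rows[0])
    if positions is None:
        positions = list(range(1, ncol + 1))
    for p in positions:
        if not 1 <= p <= ncol:
            raise IndexError(f"position {p} outside alignment (1..{ncol})")
    records = []
    for p in positions:
        col = [r[p - 1] for r in rows if r[p - 1] not in "-.X"]
        total = len(col)
        for res, cnt in sorted(pd.Series(col).value_counts().items()):
            records.append(
                {"position": p, "residue": res, "count": int(cnt),
                 "frequency": cnt / total}
            )
    invariant = [
        p for p in range(1, ncol + 1)
        if len({r[p - 1] for r in rows} - {"-", ".", "X"}) == 1
    ]
    return pd.DataFrame(records), invariant
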