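#!/usr/bin/env python
"""Lineage assignment and nomenclature: JC distance matrix over the aligned
coding sequences, neighbor-joining tree with 1,000 bootstrap replicates,
supported-clade lineage delimitation, and allele naming under the
four-field grammar.

Writes the newick tree, lineage table, and name assignments to
results/phylo/."""

from pathlib import Path

import pandas as pd

from lilrseq import phylo
from lilrseq.nomenclature import assign_allele_names, format_name
from lilrseq.synthetic import SimConfig, simulate_allele_set

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cfg = SimConfig(seed=1, ccs_error_rate=0.001)
    truth = simulate_allele_set(cfg)
    aln = truth.cds_alignment
    dm = phylo.distance_matrix(aln, "JC")
    newick, support = phylo.bootstrap_support(aln, n_reps=1000, seed=1)
    asn = phylo.assign_lineages(newick, dm, support)
    names = assign_allele_names(truth.alleles, asn.lineage_of,
                                prefix=cfg.species, gene=cfg.gene)
    out = BASE / "phylo"
    out.mkdir(parents=True, exist_ok=True)
    (out / "alleles.nwk").write_text(newick + "\n")
    true_of = {r.name: r.lineage for r in truth.alleles}
    table = pd.DataFrame([
        {"allele": a, "lineage": l, "support": asn.support[l],
         "true_lineage": true_of[a], "name": format_name(names[a])}
        for a, l in sorted(asn.lineage_of.items())
    ])
    table.to_csv(out / "lineages.tsv", sep="\t", index=False)
    agree = (table.groupby("true_lineage").lineage.nunique() == 1).all()
    print(f"{len(asn.clades)} lineages delimited "
          f"(bootstrap >= 0.7, intra-lineage JC <= 0.04); "
          f"agreement with simulated lineages: {'exact' if agree else 'PARTIAL'}")
    print(table.to_string(index=False))
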