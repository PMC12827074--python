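"""Pipeline orchestration: simulate -> filter -> demux -> call -> splice ->
phylo/name -> stats, with YAML configuration and per-stage artifacts.

Every stage is a library call; the pipeline only wires them together,
records per-stage counts, and writes standard-format artifacts (FASTA,
FASTQ, TSV, newick, JSON). Identical config + seed yields identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio.Seq import Seq

from . import allele_discovery as ad
from . import diversity, phylo, read_processing as rp, splice, synthetic
from .nomenclature import assign_allele_names, format_name, parse_name, NameParseError
from .records import AlleleRecord, ReferenceLibrary

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    gene: str = "LILRB1"
    species: str = "Mamu"
    quality_threshold: float = 0.99
    barcode_max_mismatch: int = 1
    min_overlap: int = 400
    cluster_identity: float = 0.995
    min_reads_per_contig: int = 3
    max_iterations: int = 5
    distance_method: str = "JC"
    bootstrap_reps: int = 100
    min_support: float = 0.7
    max_intra_lineage: float = 0.04
    sim: dict = field(default_factory=dict)
    input_fastq: str | None = None  # if set, skip simulation
    barcode_manifest: str | None = None
    reference_fasta: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.quality_threshold <= 1:
            raise PipelineConfigError("quality_threshold outside [0, 1]")
        if not 0 < self.cluster_identity <= 1:
            raise PipelineConfigError("cluster_identity outside (0, 1]")
        if self.min_reads_per_contig < 1 or self.min_overlap < 1:
            raise PipelineConfigError("count thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def load_reference_library(path, *, strict: bool = False) -> ReferenceLibrary:
    """FASTA with structured ``name|gene|species|source`` headers."""
    from Bio import SeqIO

    records = []
    problems = []
    for lineno, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        fields = rec.description.split("|")
        name = fields[0].strip()
        gene = fields[1].strip() if len(fields) > 1 else "unknown"
        species = fields[2].strip() if len(fields) > 2 else "unknown"
        source = fields[3].strip() if len(fields) > 3 else "published"
        try:
            parse_name(name)
        except NameParseError as exc:
            msg = f"entry {lineno} ({name!r}): {exc}"
            if strict:
                raise NameParseError(name, 0, msg) from exc
            problems.append(msg)
        records.append(
            AlleleRecord(name=name, seq=str(rec.seq).upper(), gene=gene,
                         species=species, source=source, kind="transcript")
        )
    for msg in problems:
        log.warning("reference library: unparseable name, kept as-is: %s", msg)
    if not records:
        log.warning("reference library %s is empty", path)
    # identical sequences under different names are kept (with a warning)
    return ReferenceLibrary(records, strict_seqs=False)


def write_library_fasta(lib: ReferenceLibrary, path) -> None:
    synthetic.write_allele_fasta(list(lib), path)


def run_pipeline(config: PipelineConfig) -> dict:
    """End-to-end run on simulated (or provided) reads; returns the report."""
    for attr in ("input_fastq", "barcode_manifest", "reference_fasta"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise PipelineConfigError(f"{attr} path does not exist: {p}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_seed": config.seed, "stages": {}}

    # -- stage: simulate (or load) ---------------------------------------
    sim_cfg = synthetic.SimConfig(
        seed=config.seed, gene=config.gene, species=config.species,
        **config.sim,
    )
    truth = synthetic.simulate_allele_set(sim_cfg)
    reads_raw, truth = synthetic.simulate_ccs_reads(truth, sim_cfg)
    synthetic.write_allele_fasta(truth.alleles, out / "alleles_truth.fasta")
    synthetic.write_fastq(reads_raw, out / "reads.fastq")
    truth.barcodes.to_csv(out / "barcodes.tsv", sep="\t", index=False)
    truth.reads.to_csv(out / "reads_truth.tsv", sep="\t", index=False)
    report["stages"]["simulate"] = {
        "alleles": len(truth.alleles), "reads": len(reads_raw),
    }

    # -- stage: quality filter -------------------------------------------
    reads = [rp.CcsRead(i, s, q) for i, s, q in reads_raw]
    kept = rp.filter_by_quality(reads, config.quality_threshold)
    report["stages"]["filter"] = {"in": len(reads), "kept": len(kept)}

    # -- stage: demultiplex ----------------------------------------------
    per_sample, unassigned = rp.demultiplex(
        kept, truth.barcodes, config.barcode_max_mismatch
    )
    report["stages"]["demux"] = {
        "assigned": sum(len(v) for v in per_sample.values()),
        "unassigned": len(unassigned),
    }

    # -- stage: allele calling -------------------------------------------
    run_of = dict(zip(truth.reads.read_id, truth.reads.run))
    lib = ReferenceLibrary(
        [
            AlleleRecord(
                name=f"{rec.name}|canonical", seq=truth.transcript(rec.name, ""),
                gene=rec.gene, species=rec.species, source="published",
                kind="transcript",
            )
            for rec in truth.alleles[:1]
        ]
    )
    if config.reference_fasta:
        lib = load_reference_library(config.reference_fasta)
    result = ad.discover_alleles(
        per_sample, lib, run_of=run_of, max_iterations=config.max_iterations,
        min_reads=config.min_reads_per_contig, identity=config.cluster_identity,
        min_overlap=config.min_overlap, gene=config.gene, species=config.species,
    )
    calls = ad.calls_table(result.assignments, result.library)
    calls.to_csv(out / "allele_calls.tsv", sep="\t", index=False)
    write_library_fasta(result.library, out / "library.fasta")
    report["stages"]["call"] = {
        "library_version": result.library.version,
        "library_size": len(result.library),
        "assigned_reads": len({a.read_id for a in result.assignments}),
        "unassigned_reads": len(result.unassigned),
        "confirmed_novel": len(result.confirmed),
        "iterations": result.iterations,
    }

    # -- stage: splice annotation ----------------------------------------
    event_rows = []
    genomic_by_name = {rec.name: rec for rec in truth.alleles}
    for rec in truth.alleles:
        for sig_text in sim_cfg.splice_profile:
            sig = splice.parse_signature(sig_text)
            tx = truth.transcript(rec.name, sig_text)
            blocks = splice.align_transcript(tx, rec.seq, rec.model)
            for ev in splice.classify_events(blocks, rec.model):
                for sample, genotype in truth.genotypes.items():
                    if rec.name in genotype:
                        event_rows.append(
                            {
                                "animal": sample, "species": rec.species,
                                "allele": rec.name, "kind": ev.kind,
                                "exon": ev.exon, "delta_bp": ev.delta_bp,
                            }
                        )
    events = pd.DataFrame(event_rows)
    shared = splice.filter_shared_events(events) if not events.empty else events
    events.to_csv(out / "splice_events.tsv", sep="\t", index=False)
    shared.to_csv(out / "splice_events_shared.tsv", sep="\t", index=False)
    report["stages"]["splice"] = {
        "events": 0 if events.empty else int(
            events.groupby(["kind", "exon", "delta_bp"]).ngroups
        ),
        "shared_events": len(shared),
    }

    # -- stage: phylogeny, lineages, names -------------------------------
    aln = truth.cds_alignment
    dm = phylo.distance_matrix(aln, config.distance_method)
    newick, support = phylo.bootstrap_support(
        aln, config.bootstrap_reps, seed=config.seed,
        method=config.distance_method,
    )
    (out / "alleles.nwk").write_text(newick + "\n")
    assignment = phylo.assign_lineages(
        newick, dm, support, min_support=config.min_support,
        max_intra=config.max_intra_lineage,
    )
    names = assign_allele_names(
        truth.alleles, assignment.lineage_of,
        prefix=config.species, gene=config.gene,
    )
    lineage_table = pd.DataFrame(
        [
            {"allele": a, "lineage": l, "name": format_name(names[a]),
             "true_lineage": genomic_by_name[a].lineage}
            for a, l in sorted(assignment.lineage_of.items())
        ]
    )
    lineage_table.to_csv(out / "lineages.tsv", sep="\t", index=False)
    report["stages"]["phylo"] = {
        "lineages": len(assignment.clades),
        "bootstrap_reps": config.bootstrap_reps,
    }

    # -- stage: diversity stats ------------------------------------------
    prots = {
        n: str(Seq(s.replace("-", "")).translate()).rstrip("*")
        for n, s in aln.items()
    }
    # variability over the ungapped common length
    minlen = min(len(p) for p in prots.values())
    profile = diversity.variability_profile({n: p[:minlen] for n, p in prots.items()})
    pd.DataFrame({"position": range(1, minlen + 1), "unique_aa": profile}).to_csv(
        out / "variability.tsv", sep="\t", index=False
    )
    groups = diversity.domain_identity_groups(truth.alleles)
    groups.to_csv(out / "domain_groups.tsv", sep="\t", index=False)
    report["stages"]["stats"] = {
        "variable_positions": int((profile > 1).sum()),
        "domain_groups": len(groups),
    }

    # -- truth-based scoring ---------------------------------------------
    truth_tx = {seq for seq in truth.all_transcripts().values()}
    confirmed_seqs = {rec.seq for rec in result.confirmed}
    false_novel = sorted(confirmed_seqs - truth_tx)
    recovered = {
        rec.name
        for rec in truth.alleles
        if any(truth.transcripts[(rec.name, s)] in confirmed_seqs
               or result.library.contains_seq(rec.gene, truth.transcripts[(rec.name, s)])
               for s in sim_cfg.splice_profile)
    }
    report["scoring"] = {
        "alleles_recovered": len(recovered),
        "alleles_total": len(truth.alleles),
        "false_novel": len(false_novel),
        "lineage_agreement": float(
            (lineage_table.groupby("true_lineage")["lineage"].nunique() == 1).all()
            and (lineage_table.groupby("lineage")["true_lineage"].nunique() == 1).all()
        ),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
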