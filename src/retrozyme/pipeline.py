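"""End-to-end orchestration: scan -> annotate -> classify/assemble -> profile.

The pipeline runs the whole analysis on either provided files or simulated
inputs and writes a reproducible bundle: locus GFF3, contig FASTA,
classification and spectrum TSVs, small-RNA profile TSVs, methylation
tables, and a run manifest with the config hash, seed and package version.
Each stage logs its headline counts so the run is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from . import annotate as ann
from . import homology, methylation, report, rna, seq_io, simulate, smallrna

logger = logging.getLogger("retrozyme")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    outdir: str = "rzk_out"
    seed: int = 0
    # genome stage: paths, or None to simulate
    genome_fasta: Optional[str] = None
    ltr_query_fasta: Optional[str] = None
    cr_query_fasta: Optional[str] = None
    hits_tsv: Optional[str] = None
    trna_3prime: Optional[str] = None
    # scan/annotate thresholds
    seed_k: int = 12
    min_identity: float = 0.70
    min_length: int = 50
    max_evalue_like: float = 1e-10
    min_ltr_len: int = 250
    max_ltr_len: int = 450
    min_cr_len: int = 100
    max_cr_len: int = 1500
    grouping_identity: float = 0.80
    significance_identity: float = 0.50
    # RNA stage
    reads_fastq: Optional[str] = None
    n_molecules: int = 150
    replication_rounds: int = 10
    error_rate: float = 0.001
    n_reads: int = 600
    read_len: int = 100
    min_overlap: int = 20
    max_extension: int = 25
    # small-RNA stage
    smallrna_fastq: Optional[str] = None
    n_smallrnas: int = 5000
    ltr_bias: float = 0.816
    # methylation stage
    clones_fasta: Optional[str] = None
    control_clones_fasta: Optional[str] = None
    n_clones: int = 20
    methylation_rates: dict = field(
        default_factory=lambda: {"CpG": 0.9, "CHG": 0.7, "CHH": 0.4}
    )
    control_rate: float = 0.05
    conversion_rate: float = 1.0

    def validate(self) -> None:
        checks = [
            (0 < self.min_identity <= 1, "min_identity in (0, 1]"),
            (self.min_length > 0, "min_length > 0"),
            (self.seed_k >= 8, "seed_k >= 8"),
            (0 < self.min_ltr_len <= self.max_ltr_len, "LTR length window ordered"),
            (0 < self.min_cr_len <= self.max_cr_len, "CR length window ordered"),
            (self.min_overlap >= 15, "min_overlap >= 15"),
            (self.max_extension >= 0, "max_extension >= 0"),
            (0 <= self.ltr_bias <= 1, "ltr_bias in [0, 1]"),
            (0 < self.conversion_rate <= 1, "conversion_rate in (0, 1]"),
            (0 <= self.error_rate < 0.05, "error_rate in [0, 0.05)"),
            (self.n_reads >= 0 and self.n_molecules > 0, "read/molecule counts"),
            (all(0 <= v <= 1 for v in self.methylation_rates.values()),
             "methylation rates in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(f"invalid configuration: expected {msg}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = _from_dict(cls, data)
        cfg.validate()
        return cfg

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns a dict with the in-memory results (loci, classifications,
    contigs, profile, methylation tables) plus the paths written.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {"paths": {}}

    def stage(name):
        def wrap(fn):
            try:
                logger.info("stage %s", name)
                return fn()
            except (ConfigError, StageError):
                raise
            except Exception as e:  # noqa: BLE001 - rewrapped with stage context
                raise StageError(name, e) from e
        return wrap

    # ---- genome: load or simulate -------------------------------------
    def genome_stage():
        if config.genome_fasta:
            scaffolds = [
                seq_io.Scaffold(i, s) for i, s in seq_io.read_fasta(config.genome_fasta)
            ]
            if not config.ltr_query_fasta:
                raise ConfigError("genome_fasta requires ltr_query_fasta")
            ltr_query = seq_io.read_fasta(config.ltr_query_fasta)[0][1]
            cr_queries = (
                dict(seq_io.read_fasta(config.cr_query_fasta))
                if config.cr_query_fasta
                else {}
            )
            trna = config.trna_3prime
            truth = None
        else:
            gcfg = simulate.GenomeSimConfig(seed=config.seed)
            scaffolds, truth = simulate.simulate_genome(gcfg)
            ltr_query = truth.templates["ltr_query"]
            cr_queries = {
                k: v for k, v in truth.templates.items() if k.startswith("cr_query")
            }
            trna = truth.templates["trna_3prime"]
        return scaffolds, ltr_query, cr_queries, trna, truth

    scaffolds, ltr_query, cr_queries, trna, truth = stage("genome")(genome_stage)
    results["ground_truth"] = truth

    def scan_stage():
        if config.hits_tsv:
            ltr_hits = homology.import_hits(config.hits_tsv)
            cr_hits = []
        else:
            ltr_hits = homology.scan_genome(
                scaffolds, ltr_query, query_id="LTR", k=config.seed_k,
                min_identity=config.min_identity, min_length=config.min_length,
            )
            cr_hits = []
            for qid, qseq in sorted(cr_queries.items()):
                cr_hits.extend(
                    homology.scan_genome(
                        scaffolds, qseq, query_id=qid, k=config.seed_k,
                        min_identity=config.min_identity, min_length=config.min_length,
                    )
                )
        ltr_hits = homology.filter_hits(
            ltr_hits, config.max_evalue_like, config.min_identity, config.min_length
        )
        logger.info("scan: %d LTR hits, %d CR hits", len(ltr_hits), len(cr_hits))
        homology.export_hits(ltr_hits + cr_hits, out / "hits.tsv")
        results["paths"]["hits"] = str(out / "hits.tsv")
        return ltr_hits, cr_hits

    ltr_hits, cr_hits = stage("scan")(scan_stage)

    def annotate_stage():
        loci = ann.annotate_genome(
            scaffolds, ltr_hits, cr_hits, trna_3prime=trna, ltr_query=ltr_query,
            min_ltr_len=config.min_ltr_len, max_ltr_len=config.max_ltr_len,
            min_cr_len=config.min_cr_len, max_cr_len=config.max_cr_len,
            grouping_identity=config.grouping_identity,
            significance_identity=config.significance_identity,
        )
        full = [l for l in loci if l.completeness == "full"]
        logger.info("annotate: %d loci (%d full)", len(loci), len(full))
        seq_io.write_gff3(loci, out / "loci.gff3",
                          {s.id: len(s) for s in scaffolds})
        results["paths"]["loci"] = str(out / "loci.gff3")
        return loci

    loci = stage("annotate")(annotate_stage)
    results["loci"] = loci
    full_loci = [l for l in loci if l.completeness == "full"]
    seqs = {s.id: s.seq for s in scaffolds}
    monomers = {
        l.id: simulate.element_monomer(l, seqs[l.scaffold_id]) for l in full_loci
    }
    # reads and small RNAs are classified against monomer references, so
    # region spans must be in monomer coordinates
    annotations = {l.id: ann.monomer_annotation(l) for l in full_loci}

    def rna_stage():
        if config.reads_fastq:
            reads = seq_io.read_fastq(config.reads_fastq)
        elif full_loci:
            rcfg = simulate.ReplicationSimConfig(
                n_molecules=config.n_molecules,
                rounds_distribution={config.replication_rounds: 1.0},
                error_rate=config.error_rate, seed=config.seed + 1,
            )
            source = monomers[sorted(monomers)[0]]
            population, _ = simulate.simulate_replication(source, rcfg)
            reads, _ = simulate.simulate_reads(
                population, config.n_reads, config.read_len, seed=config.seed + 2
            )
        else:
            return None
        cls, dropped = rna.align_reads_to_refs(reads, monomers, circular=True)
        for c in cls:
            c.region = rna.assign_region(c, annotations)
        spectrum = rna.mismatch_spectrum(cls)
        logger.info("classify: %d reads classified, %d dropped", len(cls), dropped)
        report.classification_table(cls).to_csv(out / "classification.tsv",
                                                sep="\t", index=False)
        report.spectrum_table(spectrum).to_csv(out / "spectrum.tsv",
                                               sep="\t", index=False)
        oriented = [
            seq_io.Read(c.read_id, r.seq if c.strand == "+" else seq_io.revcomp(r.seq))
            for c, r in zip(cls, [next(x for x in reads if x.id == c.read_id)
                                  for c in cls])
        ]
        contigs = rna.assemble_strict(oriented, config.min_overlap, config.max_extension)
        rna.audit_contigs(contigs, oriented, config.max_extension)
        genome_rows = rna.contigs_vs_genome(contigs, monomers)
        n_identical = sum(r["identical"] for r in genome_rows)
        logger.info("assemble: %d contigs, %d identical to genome",
                    len(contigs), n_identical)
        seq_io.write_fasta([(c.id, c.seq) for c in contigs], out / "contigs.fasta")
        report.contig_table(contigs, genome_rows).to_csv(
            out / "contigs.tsv", sep="\t", index=False
        )
        results["paths"].update(
            classification=str(out / "classification.tsv"),
            spectrum=str(out / "spectrum.tsv"),
            contigs=str(out / "contigs.fasta"),
        )
        return {"classifications": cls, "spectrum": spectrum,
                "contigs": contigs, "contigs_vs_genome": genome_rows,
                "n_dropped": dropped}

    results["rna"] = stage("rna")(rna_stage)

    def smallrna_stage():
        if not full_loci:
            return None
        target = full_loci[0]
        if config.smallrna_fastq:
            sreads = seq_io.read_fastq(config.smallrna_fastq)
        else:
            # small RNAs are processed from retrozyme RNA, i.e. the monomer
            # (one LTR + CR), not from the two-LTR genomic element
            monomer = monomers[target.id]
            L = len(target.ltr5)
            sreads, _ = simulate.simulate_small_rnas(
                monomer, [(0, L)], (L, len(monomer)), config.n_smallrnas,
                ltr_bias=config.ltr_bias, seed=config.seed + 3,
            )
        profile = smallrna.profile_small_rnas(
            sreads, {l.id: monomers[l.id] for l in full_loci}, annotations
        )
        logger.info("smallrna: %d matched, LTR fraction %.3f",
                    profile.n_total, profile.ltr_fraction)
        lengths, regions = report.smallrna_tables(profile)
        lengths.to_csv(out / "smallrna_lengths.tsv", sep="\t", index=False)
        regions.to_csv(out / "smallrna_regions.tsv", sep="\t", index=False)
        results["paths"]["smallrna"] = str(out / "smallrna_lengths.tsv")
        return profile

    results["smallrna"] = stage("smallrna")(smallrna_stage)

    def methylation_stage():
        if config.clones_fasta:
            clones = dict(seq_io.read_fasta(config.clones_fasta))
            ref = monomers[sorted(monomers)[0]][: 350] if full_loci else None
            control = (
                dict(seq_io.read_fasta(config.control_clones_fasta))
                if config.control_clones_fasta
                else {}
            )
            control_ref = ref
        elif full_loci:
            target = full_loci[0]
            ref = seqs[target.scaffold_id][target.ltr5.start : target.ltr5.end]
            clones, _ = simulate.simulate_bisulfite_clones(
                ref, config.methylation_rates, config.n_clones,
                config.conversion_rate, seed=config.seed + 4,
            )
            control_ref = ref
            control_rates = {c: config.control_rate for c in methylation.CONTEXTS}
            control, _ = simulate.simulate_bisulfite_clones(
                control_ref, control_rates, config.n_clones,
                config.conversion_rate, seed=config.seed + 5,
            )
        else:
            return None
        table = methylation.call_methylation(clones, ref, reference_id="target_LTR")
        report.methylation_matrix(table).to_csv(out / "methylation_matrix.tsv", sep="\t")
        report.methylation_summary(table).to_csv(
            out / "methylation_summary.tsv", sep="\t", index=False
        )
        results["paths"]["methylation"] = str(out / "methylation_summary.tsv")
        outcome = {"target": table}
        if control:
            ctable = methylation.call_methylation(control, control_ref,
                                                  reference_id="control")
            u, p = methylation.compare_methylation(table, ctable)
            logger.info("methylation: target %.1f%%, control %.1f%%, p=%.2e",
                        table.pct_methylated, ctable.pct_methylated, p)
            outcome.update(control=ctable, U=u, p_value=p)
        return outcome

    results["methylation"] = stage("methylation")(methylation_stage)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.resolved(), sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": results["paths"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["paths"]["manifest"] = str(out / "manifest.json")
    return results
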