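"""End-to-end pipeline orchestration and the simulation entry point.

Stage order: quality trim -> contaminant screen -> length routing -> miRNA
matching (short pool) -> MAPQ filter -> tRNA overlap -> Ensembl overlap ->
coverage-uniformity (mcv) filter -> quantification/summaries -> backsplice
detection on the reads left unannotated.  Every input read is accounted for
in exactly one terminal category, and a run with a fixed seed and
configuration serializes to byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as evio
from .annotate import (
    Alignment,
    ENSEMBL,
    FeatureIndex,
    FeatureModel,
    GTRNADB,
    filter_mapq,
    match_mirna,
    overlap_assign,
    resolve_annotation,
)
from .circrna import classify_vs_reference, detect_backsplice, filter_junctions
from .mcv import bin_counts, mcv_filter
from .preprocess import (
    ContaminantIndex,
    route_by_length,
    screen_contaminants,
    trim_read,
)
from .quantify import (
    SampleStats,
    biotype_distribution,
    count_features,
    normalize_per_100k,
)
from .simdata import SimConfig, make_reference, simulate_sample

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "simulate"]

ACCOUNTING_CATEGORIES = (
    "removed_by_trim",
    "removed_by_screen",
    "discarded_short",
    "mirbase_assigned",
    "mapq_removed",
    "trna_assigned",
    "ensembl_assigned",
    "unannotated",
)


@dataclass
class PipelineConfig:
    """All numeric rules of the pipeline plus reference paths.

    Defaults are the pipeline's stated operating points: 12-25 nt short-pool
    bounds, Phred-15 mean over 30-base trimming windows, MAPQ >= 20, 10 mcv
    bins at cutoff 0.7, >=2-read inclusion (>=10 for the high-coverage
    view), >=2-read circRNA support, Ct ceiling 35.
    """

    min_len: int = 12
    max_len: int = 25
    trim_window: int = 30
    trim_threshold: float = 15.0
    screen_k: int = 18
    min_mapq: int = 20
    n_bins: int = 10
    mcv_cutoff: float = 0.7
    min_reads_table: int = 2
    min_reads_pie: int = 10
    min_circ_support: int = 2
    circ_anchor_len: int = 20
    ct_ceiling: float = 35.0
    rpm_denominator: str = "post_filter"  # raw | post_filter | mapped
    stranded: bool = False
    seed: int = 0
    genome_fasta: Optional[str] = None
    features_gtf: Optional[str] = None
    mirna_fasta: Optional[str] = None
    trna_bed: Optional[str] = None
    contaminants_fasta: Optional[str] = None
    circ_reference_bed: Optional[str] = None

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        for name in (
            "min_len", "trim_window", "n_bins", "min_reads_table",
            "min_reads_pie", "min_circ_support", "circ_anchor_len",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.mcv_cutoff <= 1):
            raise ValueError("mcv_cutoff must be in (0, 1]")
        if self.rpm_denominator not in ("raw", "post_filter", "mapped"):
            raise ValueError("rpm_denominator must be raw|post_filter|mapped")

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as out:
            yaml.safe_dump(dataclasses.asdict(self), out, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        config = cls(**data)
        config.validate()
        return config


@dataclass
class RunReport:
    """Everything one pipeline run produces."""

    sample_stats: SampleStats
    accounting: dict[str, int]
    assignments: list
    counts_table: dict[str, int]
    normalized_per_100k: dict[str, float]
    mcv_table: pd.DataFrame
    mcv_retained: set[str]
    mcv_removed: set[str]
    biotype_summary_table: object
    biotype_summary_pie: object
    circ_classifications: list
    n_reads: int

    def accounting_conserved(self) -> bool:
        return sum(self.accounting.values()) == self.n_reads

    def to_json(self) -> str:
        payload = {
            "n_reads": self.n_reads,
            "accounting": self.accounting,
            "sample_stats": {
                "sample_id": self.sample_stats.sample_id,
                "raw_reads": self.sample_stats.raw_reads,
                "post_filter_reads": self.sample_stats.post_filter_reads,
                "short_pool": self.sample_stats.short_pool,
                "mirbase_mapped": self.sample_stats.mirbase_mapped,
                "reads_other": self.sample_stats.reads_other,
                "ensembl_mapped": self.sample_stats.ensembl_mapped,
                "pct_removed_by_filter": self.sample_stats.pct_removed_by_filter,
                "pct_rrna": self.sample_stats.pct_rrna,
            },
            "counts_min_reads": self.counts_table,
            "normalized_per_100k": {
                k: round(v, 6) for k, v in self.normalized_per_100k.items()
            },
            "mcv_retained": sorted(self.mcv_retained),
            "mcv_removed": sorted(self.mcv_removed),
            "biotype_major_pct_table": self.biotype_summary_table.major_pct,
            "biotype_major_pct_pie": self.biotype_summary_pie.major_pct,
            "circ": [
                {
                    "chrom": c.junction.chrom,
                    "start": c.junction.start,
                    "end": c.junction.end,
                    "strand": c.junction.strand,
                    "support": c.junction.support,
                    "class": c.circ_class,
                    "matched_reference_id": c.matched_reference_id,
                }
                for c in self.circ_classifications
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _load_references(config: PipelineConfig):
    missing = [
        name
        for name in ("genome_fasta", "features_gtf", "mirna_fasta",
                     "trna_bed", "contaminants_fasta", "circ_reference_bed")
        if getattr(config, name) is None or not Path(getattr(config, name)).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing reference inputs: {', '.join(missing)}")
    genome = dict(evio.read_fasta(config.genome_fasta))
    features = evio.read_gtf(config.features_gtf)
    mirnas = evio.read_fasta(config.mirna_fasta)
    trna = evio.read_bed(config.trna_bed)
    contaminants = evio.read_fasta(config.contaminants_fasta)
    circ_ref = evio.read_bed(config.circ_reference_bed)
    return genome, features, mirnas, trna, contaminants, circ_ref


def run_pipeline(
    config: PipelineConfig,
    fastq: str | os.PathLike,
    sam: str | os.PathLike,
    out_dir: str | os.PathLike | None = None,
) -> RunReport:
    """Run the full annotation pipeline on one sample.

    ``fastq`` holds the reads; ``sam`` holds their (externally produced)
    genome alignments, looked up per read after the miRNA stage.  When
    ``out_dir`` is given, all tables and a JSON report are written there
    deterministically.
    """
    config.validate()
    genome, features, mirnas, trna_intervals, contaminants, circ_ref = (
        _load_references(config)
    )
    reads = evio.read_fastq(fastq)
    alignments = evio.read_sam(sam)
    aln_by_read: dict[str, Alignment] = {}
    for aln in alignments:
        aln_by_read.setdefault(aln.read_id, aln)

    accounting = {cat: 0 for cat in ACCOUNTING_CATEGORIES}

    # stage 1: quality trimming (reads trimmed to nothing are removed)
    trimmed = []
    for read in reads:
        t = trim_read(read, window=config.trim_window, threshold=config.trim_threshold)
        if len(t) == 0:
            accounting["removed_by_trim"] += 1
        else:
            trimmed.append(t)

    # stage 2: contaminant (rRNA/repeat) screen
    screen_index = ContaminantIndex(contaminants, k=config.screen_k)
    screen = screen_contaminants(trimmed, screen_index)
    accounting["removed_by_screen"] = len(screen.removed)

    # stage 3: length routing
    routing = route_by_length(screen.kept, config.min_len, config.max_len)
    accounting["discarded_short"] = routing.n_discarded

    # stage 4: miRNA matching on the short pool; unmatched short-pool reads
    # fall through to the genome-annotation path
    assignments = []
    genome_pool = list(routing.long_pool)
    for read in routing.short_pool:
        hit = match_mirna(read, mirnas)
        if hit is not None:
            assignments.append(hit)
            accounting["mirbase_assigned"] += 1
        else:
            genome_pool.append(read)

    # stages 5-7: MAPQ filter, then tRNA-before-Ensembl overlap annotation
    trna_features = [
        FeatureModel(id=name, chrom=chrom, strand=strand,
                     exons=((start, end),), biotype="tRNA", source=GTRNADB)
        for chrom, start, end, strand, name in trna_intervals
    ]
    trna_ids = {f.id for f in trna_features}
    ensembl_features = [f for f in features if f.source == ENSEMBL]
    index = FeatureIndex(trna_features + ensembl_features)
    feature_map = index.features

    unannotated = []
    aligned_reads: dict[str, Alignment] = {}
    for read in genome_pool:
        aln = aln_by_read.get(read.id)
        if aln is None:
            unannotated.append(read)
            continue
        if not filter_mapq([aln], config.min_mapq):
            accounting["mapq_removed"] += 1
            continue
        hits = overlap_assign(aln, index, stranded=config.stranded)
        trna_hits = [h for h in hits if h[0] in trna_ids]
        ensembl_hits = [h for h in hits if h[0] not in trna_ids]
        assignment = resolve_annotation(read.id, None, trna_hits, ensembl_hits,
                                        feature_map)
        if assignment is None:
            unannotated.append(read)
            continue
        assignments.append(assignment)
        aligned_reads[read.id] = aln
        if assignment.source == GTRNADB:
            accounting["trna_assigned"] += 1
        else:
            accounting["ensembl_assigned"] += 1
    accounting["unannotated"] = len(unannotated)

    # stage 8: mcv (coverage-uniformity) filter over Ensembl-annotated
    # features; miRBase/GtRNAdb assignments are exempt by pipeline order
    ensembl_assignments = [a for a in assignments if a.source == ENSEMBL]
    aln_per_feature: dict[str, list[Alignment]] = {}
    for a in ensembl_assignments:
        aln = aligned_reads.get(a.read_id)
        if aln is not None:
            aln_per_feature.setdefault(a.feature_id, []).append(aln)
    profiles = []
    for fid, alns in sorted(aln_per_feature.items()):
        try:
            profiles.append(bin_counts(alns, feature_map[fid], config.n_bins))
        except ValueError as err:
            warnings.warn(str(err))
    retained, removed = mcv_filter(profiles, config.mcv_cutoff)
    mcv_rows = [
        {
            "feature_id": p.feature_id,
            **{f"bin_{i + 1}": c for i, c in enumerate(p.bin_counts)},
            "total_reads": p.total_reads,
            "mcv_score": None if p.mcv_score is None else round(p.mcv_score, 6),
            "retained": p.feature_id in retained,
        }
        for p in profiles
    ]
    mcv_table = pd.DataFrame(mcv_rows)

    # stage 9: quantification and summaries
    ensembl_retained = [a for a in ensembl_assignments if a.feature_id in retained]
    counts = count_features(ensembl_retained, min_reads=config.min_reads_table)
    denominator = sum(counts.values())
    normalized = (
        normalize_per_100k(counts, denominator) if denominator > 0 else {}
    )
    summary_table = biotype_distribution(assignments, config.min_reads_table)
    summary_pie = biotype_distribution(assignments, config.min_reads_pie)

    stats = SampleStats(
        sample_id=Path(fastq).stem,
        raw_reads=len(reads),
        post_filter_reads=len(screen.kept),
        short_pool=routing.n_short,
        mirbase_mapped=accounting["mirbase_assigned"],
        ensembl_mapped=accounting["ensembl_assigned"],
        rrna_removed=accounting["removed_by_screen"],
    )

    # stage 10: backsplice detection on the unannotated remainder
    detection = detect_backsplice(unannotated, genome, config.circ_anchor_len)
    junctions = filter_junctions(detection.junctions, config.min_circ_support)
    classifications = [classify_vs_reference(j, circ_ref) for j in junctions]

    report = RunReport(
        sample_stats=stats,
        accounting=accounting,
        assignments=assignments,
        counts_table=counts,
        normalized_per_100k=normalized,
        mcv_table=mcv_table,
        mcv_retained=retained,
        mcv_removed=removed,
        biotype_summary_table=summary_table,
        biotype_summary_pie=summary_pie,
        circ_classifications=classifications,
        n_reads=len(reads),
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    if len(report.mcv_table):
        evio.write_table(report.mcv_table, out_dir / "mcv_scores.tsv")
    assign_rows = pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "source": a.source,
                "feature_id": a.feature_id,
                "biotype": a.biotype,
                "major_category": a.major_category,
                "subcategory": a.subcategory or ".",
                "misc_subtype": a.misc_subtype or ".",
            }
            for a in report.assignments
        ]
    )
    if len(assign_rows):
        evio.write_table(assign_rows, out_dir / "assignments.tsv")
    circ_rows = pd.DataFrame(
        [
            {
                "chrom": c.junction.chrom,
                "start": c.junction.start,
                "end": c.junction.end,
                "name": c.matched_reference_id or ".",
                "support": c.junction.support,
                "strand": c.junction.strand,
                "class": c.circ_class,
            }
            for c in report.circ_classifications
        ]
    )
    if len(circ_rows):
        evio.write_table(circ_rows, out_dir / "circ_junctions.tsv")


def simulate(config: SimConfig, out_dir: str | os.PathLike) -> dict[str, str]:
    """Generate the complete fixture set for one synthetic sample.

    Writes genome FASTA, feature GTF, mature-miRNA FASTA, tRNA and circRNA
    reference BEDs, contaminant FASTA, the sample FASTQ, truth SAM and truth
    TSV, plus a ready-to-run pipeline YAML; returns the path manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_reference(config)
    sim = simulate_sample(bundle, config)

    paths = {
        "genome_fasta": str(out / "genome.fa"),
        "features_gtf": str(out / "features.gtf"),
        "mirna_fasta": str(out / "mirnas.fa"),
        "trna_bed": str(out / "trna.bed"),
        "contaminants_fasta": str(out / "contaminants.fa"),
        "circ_reference_bed": str(out / "circ_reference.bed"),
        "fastq": str(out / "sample.fastq"),
        "sam": str(out / "sample.sam"),
        "truth": str(out / "truth.tsv"),
        "config": str(out / "pipeline.yaml"),
    }
    evio.write_fasta(bundle.genome.items(), paths["genome_fasta"])
    evio.write_gtf(bundle.features, paths["features_gtf"])
    evio.write_fasta(bundle.mirnas, paths["mirna_fasta"])
    evio.write_bed(bundle.trna_intervals, paths["trna_bed"])
    evio.write_fasta(bundle.contaminants, paths["contaminants_fasta"])
    evio.write_bed(bundle.circ_reference, paths["circ_reference_bed"])
    evio.write_fastq(sim.reads, paths["fastq"])
    sequences = {r.id: r.sequence for r in sim.reads}
    evio.write_sam(sim.alignments, bundle.genome, paths["sam"], sequences)
    evio.write_truth(sim.truth, paths["truth"])

    pipe_config = PipelineConfig(
        seed=config.seed,
        screen_k=config.screen_k,
        genome_fasta=paths["genome_fasta"],
        features_gtf=paths["features_gtf"],
        mirna_fasta=paths["mirna_fasta"],
        trna_bed=paths["trna_bed"],
        contaminants_fasta=paths["contaminants_fasta"],
        circ_reference_bed=paths["circ_reference_bed"],
    )
    pipe_config.to_yaml(paths["config"])
    return paths
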