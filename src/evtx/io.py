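"""File I/O for the pipeline's standard formats.

FASTQ and SAM go through pysam, FASTA through Biopython, GTF parsing through
gffutils, BED through pandas.  All coordinates are 0-based half-open in
memory; GTF is written 1-based closed and SAM 1-based as the formats
require.  Tabular pipeline outputs are TSV with '#'-prefixed header lines.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Alignment, ENSEMBL, FeatureModel
from .preprocess import Read
from .simdata import TruthRecord

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_sam",
    "write_sam",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_truth",
    "write_truth",
    "write_table",
]


def read_fastq(path: str | os.PathLike) -> list[Read]:
    reads = []
    with pysam.FastxFile(str(path)) as handle:
        for entry in handle:
            quals = tuple(entry.get_quality_array() or ())
            reads.append(Read(entry.name, entry.sequence or "", quals))
    return reads


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for read in reads:
            out.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality_string}\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_sam(path: str | os.PathLike) -> list[Alignment]:
    """Mapped records from a SAM file as 0-based half-open alignments."""
    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                )
            )
    return alignments


def write_sam(
    alignments: Sequence[Alignment],
    genome: Mapping[str, str],
    path: str | os.PathLike,
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Write alignments as headered SAM (coordinates converted to 1-based)."""
    chroms = list(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    ref_ids = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = ref_ids[aln.chrom]
            rec.reference_start = aln.start
            rec.mapping_quality = aln.mapq
            length = aln.end - aln.start
            rec.cigartuples = [(0, length)]
            seq = (
                sequences.get(aln.read_id)
                if sequences is not None
                else genome[aln.chrom][aln.start : aln.end]
            )
            if seq is not None and len(seq) == length:
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * length)
            out.write(rec)


def write_gtf(features: Iterable[FeatureModel], path: str | os.PathLike) -> None:
    """Write features as exon records (1-based closed) with gene_biotype and
    feature_source attributes."""
    with open(path, "w") as out:
        for f in features:
            for start, end in f.exons:
                attrs = (
                    f'gene_id "{f.id}"; transcript_id "{f.id}"; '
                    f'gene_biotype "{f.biotype}"; feature_source "{f.source}";'
                )
                out.write(
                    f"{f.chrom}\tevtx\texon\t{start + 1}\t{end}\t.\t{f.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | os.PathLike) -> list[FeatureModel]:
    """Parse exon records into feature models, grouping by transcript_id."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        entry = grouped.setdefault(
            tid,
            {
                "chrom": exon.seqid,
                "strand": exon.strand,
                "biotype": exon.attributes.get("gene_biotype", ["unknown"])[0],
                "source": exon.attributes.get("feature_source", [ENSEMBL])[0],
                "exons": [],
            },
        )
        entry["exons"].append((exon.start - 1, exon.end))
    features = []
    for tid in sorted(grouped):
        entry = grouped[tid]
        features.append(
            FeatureModel(
                id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=tuple(sorted(entry["exons"])),
                biotype=entry["biotype"],
                source=entry["source"],
            )
        )
    return features


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, str]], path: str | os.PathLike
) -> None:
    """Write (chrom, start, end, strand, id) tuples as BED6 (0-based)."""
    rows = [
        {"chrom": c, "start": s, "end": e, "name": name, "score": 0, "strand": strand}
        for c, s, e, strand, name in intervals
    ]
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str, str]]:
    """Read BED6 into (chrom, start, end, strand, id) tuples."""
    if os.path.getsize(path) == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS, comment="#")
    return [
        (r.chrom, int(r.start), int(r.end), str(r.strand), str(r.name))
        for r in df.itertuples(index=False)
    ]


_TRUTH_COLS = ["read_id", "feature_id", "biotype", "is_contaminant", "is_backsplice"]


def write_truth(truth: Sequence[TruthRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        out.write("#" + "\t".join(_TRUTH_COLS) + "\n")
        for t in truth:
            out.write(
                f"{t.read_id}\t{t.feature_id}\t{t.biotype}\t"
                f"{int(t.is_contaminant)}\t{int(t.is_backsplice)}\n"
            )


def read_truth(path: str | os.PathLike) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return [
        TruthRecord(
            str(r.read_id),
            "" if pd.isna(r.feature_id) else str(r.feature_id),
            "" if pd.isna(r.biotype) else str(r.biotype),
            bool(r.is_contaminant),
            bool(r.is_backsplice),
        )
        for r in df.itertuples(index=False)
    ]


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """TSV with a '#'-prefixed header line."""
    with open(path, "w") as out:
        out.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(out, sep="\t", header=False, index=False)
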