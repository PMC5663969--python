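"""Hierarchical read annotation: miRNA matching, MAPQ filtering, overlap
assignment and biotype grouping.

Annotation respects the source-database hierarchy of the pipeline: mature
miRNAs (miRBase stand-in) take precedence over tRNA intervals (GtRNAdb
stand-in), which take precedence over all other transcript annotations
(Ensembl-style biotypes).  Every read receives at most one assignment.
Biotypes are grouped into four major categories (protein coding, pseudogene,
long noncoding, short noncoding); short-noncoding assignments carry a
subcategory, and misc_RNA is further split into Y_RNA / SRP_7SL_RNA /
Vault_RNA / 7SK_RNA.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "Alignment",
    "FeatureModel",
    "Assignment",
    "GroupedBiotype",
    "FeatureIndex",
    "MIRBASE",
    "GTRNADB",
    "ENSEMBL",
    "load_biotype_table",
    "group_biotype",
    "match_mirna",
    "filter_mapq",
    "overlap_assign",
    "resolve_annotation",
]

MIRBASE = "miRBase"
GTRNADB = "GtRNAdb"
ENSEMBL = "Ensembl"

UNMAPPED_BIOTYPE = "unmapped_biotype"


@dataclass(frozen=True)
class Alignment:
    """A read placed on a reference interval (0-based half-open)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: start {self.start} >= end {self.end}")
        if self.mapq < 0:
            raise ValueError(f"{self.read_id}: negative mapq")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureModel:
    """A transcript/feature: ordered non-overlapping exons plus a biotype."""

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str
    source: str = ENSEMBL

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"feature {self.id}: empty exon ({start},{end})")
            if start < prev_end:
                raise ValueError(f"feature {self.id}: exons overlap or are unsorted")
            prev_end = end
        if self.spliced_length < 1:
            raise ValueError(f"feature {self.id}: zero spliced length")

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


class GroupedBiotype(NamedTuple):
    major_category: str
    subcategory: Optional[str]
    misc_subtype: Optional[str]


@dataclass(frozen=True)
class Assignment:
    """The single annotation a read receives."""

    read_id: str
    feature_id: str
    source: str
    biotype: str
    major_category: str
    subcategory: Optional[str] = None
    misc_subtype: Optional[str] = None


def load_biotype_table() -> dict[str, GroupedBiotype]:
    """Load the editable biotype -> category mapping shipped with the package."""
    table: dict[str, GroupedBiotype] = {}
    path = resources.files("evtx").joinpath("data/biotype_groups.tsv")
    with path.open() as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            biotype, major, sub, misc = row
            table[biotype] = GroupedBiotype(
                major, None if sub == "." else sub, None if misc == "." else misc
            )
    return table


_BIOTYPE_TABLE: dict[str, GroupedBiotype] | None = None


def _biotype_table() -> dict[str, GroupedBiotype]:
    global _BIOTYPE_TABLE
    if _BIOTYPE_TABLE is None:
        _BIOTYPE_TABLE = load_biotype_table()
    return _BIOTYPE_TABLE


def group_biotype(biotype: str, source: str = ENSEMBL) -> GroupedBiotype:
    """Map a biotype string (plus its source database) to the reporting
    hierarchy (major category, subcategory, misc_RNA subtype).

    Mature miRBase hits and GtRNAdb tRNAs are short-noncoding regardless of
    the biotype string.  Unknown Ensembl biotypes map to the explicit
    ``unmapped_biotype`` category with a warning so they can be counted
    separately rather than silently dropped.
    """
    if source == MIRBASE:
        return GroupedBiotype("short_noncoding", "miRNA", None)
    if source == GTRNADB:
        return GroupedBiotype("short_noncoding", "tRNA", None)
    table = _biotype_table()
    if biotype not in table:
        warnings.warn(f"unmapped biotype {biotype!r}; counted as {UNMAPPED_BIOTYPE}")
        return GroupedBiotype(UNMAPPED_BIOTYPE, None, None)
    return table[biotype]


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def match_mirna(
    read,
    mirna_reference: Sequence[tuple[str, str]],
    max_mismatch: int = 1,
    allow_3p_overhang: int = 2,
) -> Optional[Assignment]:
    """Match a short-pool read against mature miRNA sequences.

    The read is anchored at the mature 5' end.  Up to ``allow_3p_overhang``
    3' bases of the read may be untemplated (ignored in the comparison), and
    up to ``max_mismatch`` substitutions are tolerated over the compared
    region; reads shorter than the mature sequence are allowed (3'-trimmed
    isoforms).  Ties are broken by fewest mismatches, then lexicographic
    miRNA id.
    """
    seq = read.sequence
    best: tuple[int, str] | None = None
    for mirna_id, mature in mirna_reference:
        candidate: int | None = None
        for overhang in range(allow_3p_overhang + 1):
            core = len(seq) - overhang
            if core < 1 or core > len(mature):
                continue
            mm = _hamming(seq[:core], mature[:core])
            if mm <= max_mismatch and (candidate is None or mm < candidate):
                candidate = mm
        if candidate is None:
            continue
        key = (candidate, mirna_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return Assignment(
        read_id=read.id,
        feature_id=best[1],
        source=MIRBASE,
        biotype="miRNA",
        major_category="short_noncoding",
        subcategory="miRNA",
    )


def filter_mapq(alignments: Sequence[Alignment], min_mapq: int = 20) -> list[Alignment]:
    """Drop alignments with Phred-scaled mapping quality below ``min_mapq``
    (low MAPQ indicates multi-locus ambiguity); order preserved."""
    return [a for a in alignments if a.mapq >= min_mapq]


class FeatureIndex:
    """Interval index over feature exons for overlap queries."""

    def __init__(self, features: Iterable[FeatureModel]):
        self.features: dict[str, FeatureModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for feature in features:
            if feature.id in self.features:
                raise ValueError(f"duplicate feature id {feature.id}")
            self.features[feature.id] = feature
            tree = self._trees.setdefault(feature.chrom, IntervalTree())
            for start, end in feature.exons:
                tree.addi(start, end, feature.id)

    def overlapping(
        self, alignment: Alignment, stranded: bool = False
    ) -> list[tuple[str, int]]:
        tree = self._trees.get(alignment.chrom)
        if tree is None:
            return []
        overlaps: dict[str, int] = {}
        for iv in tree.overlap(alignment.start, alignment.end):
            feature = self.features[iv.data]
            if stranded and feature.strand != alignment.strand:
                continue
            bp = min(alignment.end, iv.end) - max(alignment.start, iv.begin)
            overlaps[iv.data] = overlaps.get(iv.data, 0) + bp
        return sorted(overlaps.items())


def overlap_assign(
    alignment: Alignment, feature_index: FeatureIndex, stranded: bool = False
) -> list[tuple[str, int]]:
    """All features whose exon union overlaps the alignment by >= 1 bp,
    with total overlap length; strand-agnostic by default (BEDTools
    intersect semantics)."""
    return feature_index.overlapping(alignment, stranded=stranded)


def _best_hit(
    hits: Sequence[tuple[str, int]], features: Mapping[str, FeatureModel]
) -> tuple[str, int]:
    # largest overlap, then shortest spliced feature, then lexicographic id
    return min(hits, key=lambda h: (-h[1], features[h[0]].spliced_length, h[0]))


def resolve_annotation(
    read_id: str,
    mirna_hit: Optional[Assignment],
    trna_hits: Sequence[tuple[str, int]],
    ensembl_hits: Sequence[tuple[str, int]],
    features: Mapping[str, FeatureModel],
) -> Optional[Assignment]:
    """Resolve a read's candidate hits into a single assignment.

    Precedence: miRBase > GtRNAdb > Ensembl.  Within a tier the hit with the
    largest overlap wins; ties go to the smallest spliced feature, then the
    lexicographically first id.  Returns ``None`` for unannotated reads.
    """
    if mirna_hit is not None:
        return mirna_hit
    for tier in (trna_hits, ensembl_hits):
        if not tier:
            continue
        feature_id, _ = _best_hit(tier, features)
        feature = features[feature_id]
        grouped = group_biotype(feature.biotype, feature.source)
        return Assignment(
            read_id=read_id,
            feature_id=feature.id,
            source=feature.source,
            biotype=feature.biotype,
            major_category=grouped.major_category,
            subcategory=grouped.subcategory,
            misc_subtype=grouped.misc_subtype,
        )
    return None
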