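"""Quantification, normalization and run summaries.

Count tables with read-support thresholds (>=2 for transcript inventories,
>=10 for the high-coverage view), reads-per-million and per-100k
normalization, nested biotype read-share distributions, the core
transcriptome (features present in every sample), NGS fold changes, and the
per-sample/Average run-accounting table.

Percentages follow the accounting conventions of the run summary: the
removed-by-filter and rRNA percentages are relative to raw reads; the short
pool and "other RNA" pools are relative to post-filter reads; miRBase-mapped
is relative to the short pool; Ensembl-mapped is relative to the "other RNA"
pool.  Printed percentages are rounded half-up to one decimal, and the
Average row averages per-sample percentages (not ratios of averaged counts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import Assignment

__all__ = [
    "SampleStats",
    "BiotypeSummary",
    "count_features",
    "rpm",
    "normalize_per_100k",
    "biotype_distribution",
    "core_transcriptome",
    "fold_change_ngs",
    "summarize_run",
    "round_half_up",
]


def round_half_up(value: float | Decimal, digits: int = 1) -> float:
    """Decimal round-half-up (the convention of printed summary tables)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: float, denominator: float) -> float:
    return round_half_up(100 * Decimal(str(numerator)) / Decimal(str(denominator)), 1)


@dataclass
class SampleStats:
    """Per-sample pipeline accounting (one run-summary row).

    ``pct_rrna`` may be supplied directly (when only the percentage is
    known) or derived from ``rrna_removed``.
    """

    sample_id: str
    raw_reads: int
    post_filter_reads: int
    short_pool: int
    mirbase_mapped: int
    ensembl_mapped: int
    rrna_removed: Optional[int] = None
    pct_rrna_given: Optional[float] = None

    @property
    def reads_other(self) -> int:
        return self.post_filter_reads - self.mirbase_mapped

    @property
    def pct_removed_by_filter(self) -> float:
        return _pct(self.raw_reads - self.post_filter_reads, self.raw_reads)

    @property
    def pct_rrna(self) -> Optional[float]:
        if self.rrna_removed is not None:
            return _pct(self.rrna_removed, self.raw_reads)
        if self.pct_rrna_given is not None:
            return round_half_up(self.pct_rrna_given, 1)
        return None

    @property
    def pct_short_pool(self) -> float:
        return _pct(self.short_pool, self.post_filter_reads)

    @property
    def pct_mirbase_of_short(self) -> float:
        return _pct(self.mirbase_mapped, self.short_pool)

    @property
    def pct_other_of_filtered(self) -> float:
        return _pct(self.reads_other, self.post_filter_reads)

    @property
    def pct_ensembl_of_other(self) -> float:
        return _pct(self.ensembl_mapped, self.reads_other)


def count_features(
    assignments: Iterable[Assignment], min_reads: int = 2
) -> dict[str, int]:
    """Read counts per feature, keeping only features supported by at least
    ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    counts = Counter(a.feature_id for a in assignments)
    return {fid: n for fid, n in sorted(counts.items()) if n >= min_reads}


def rpm(count: float, total: float) -> float:
    """Reads per million: count * 1e6 / total."""
    if total <= 0:
        raise ValueError("total reads must be > 0")
    return count * 1_000_000 / total


def normalize_per_100k(
    counts: Mapping[str, float], denominator: float
) -> dict[str, float]:
    """Normalize feature counts to 100,000 reads/sample relative to the
    total mapped-transcript count."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return {fid: c * 100_000 / denominator for fid, c in counts.items()}


@dataclass
class BiotypeSummary:
    """Nested read-share distribution with distinct-transcript counts.

    Three pie levels, each summing to 100%: major categories; the
    short-noncoding subcategories; the misc_RNA subtypes.
    """

    min_reads: int
    major_pct: dict[str, float]
    short_subcategory_pct: dict[str, float]
    misc_subtype_pct: dict[str, float]
    transcript_counts: dict[str, int]
    read_counts: dict[str, int]


def _shares(counter: Counter) -> dict[str, float]:
    total = sum(counter.values())
    if total == 0:
        return {}
    return {k: 100 * v / total for k, v in sorted(counter.items())}


def biotype_distribution(
    assignments: Sequence[Assignment], min_reads: int = 2
) -> BiotypeSummary:
    """Read-share distributions per category, at a feature-support threshold.

    Features with fewer than ``min_reads`` reads are excluded before shares
    are computed, mirroring the >=2-read inventory and >=10-read
    high-coverage views of the run reports.
    """
    kept_features = set(count_features(assignments, min_reads=min_reads))
    kept = [a for a in assignments if a.feature_id in kept_features]

    major = Counter(a.major_category for a in kept)
    short_sub = Counter(
        a.subcategory
        for a in kept
        if a.major_category == "short_noncoding" and a.subcategory
    )
    misc = Counter(a.misc_subtype for a in kept if a.misc_subtype)
    transcripts = Counter()
    reads = Counter()
    feature_category: dict[str, str] = {}
    for a in kept:
        reads[a.major_category] += 1
        feature_category.setdefault(a.feature_id, a.major_category)
    for fid in kept_features:
        transcripts[feature_category[fid]] += 1
    return BiotypeSummary(
        min_reads=min_reads,
        major_pct=_shares(major),
        short_subcategory_pct=_shares(short_sub),
        misc_subtype_pct=_shares(misc),
        transcript_counts=dict(sorted(transcripts.items())),
        read_counts=dict(sorted(reads.items())),
    )


def core_transcriptome(
    per_sample_feature_sets: Sequence[set[str]],
) -> tuple[set[str], float]:
    """Features present in every sample, and their fraction of the union."""
    if len(per_sample_feature_sets) < 2:
        raise ValueError("core transcriptome needs >= 2 samples")
    union = set().union(*per_sample_feature_sets)
    if not union:
        raise ValueError("core fraction undefined: empty union")
    core = set.intersection(*map(set, per_sample_feature_sets))
    return core, len(core) / len(union)


def fold_change_ngs(rpm_a: float, rpm_b: float) -> float:
    """NGS fold change between two normalized abundances (rpm_a / rpm_b)."""
    if rpm_b <= 0:
        raise ValueError("denominator rpm must be > 0")
    return rpm_a / rpm_b


_COUNT_COLS = [
    "raw_reads",
    "post_filter_reads",
    "short_pool",
    "mirbase_mapped",
    "reads_other",
    "ensembl_mapped",
]
_PCT_COLS = [
    "pct_removed_by_filter",
    "pct_rrna",
    "pct_short_pool",
    "pct_mirbase_of_short",
    "pct_other_of_filtered",
    "pct_ensembl_of_other",
]


def summarize_run(per_sample: Sequence[SampleStats]) -> pd.DataFrame:
    """Run-summary table: one row per sample plus an Average row.

    Count averages are arithmetic means of per-sample counts (half-up to
    whole reads); percentage averages are arithmetic means of the
    per-sample percentages (to one decimal) — not ratios of averaged counts.
    """
    if not per_sample:
        raise ValueError("at least one sample required")
    rows = []
    for s in per_sample:
        rows.append(
            {
                "sample": s.sample_id,
                "raw_reads": s.raw_reads,
                "post_filter_reads": s.post_filter_reads,
                "short_pool": s.short_pool,
                "mirbase_mapped": s.mirbase_mapped,
                "reads_other": s.reads_other,
                "ensembl_mapped": s.ensembl_mapped,
                "pct_removed_by_filter": s.pct_removed_by_filter,
                "pct_rrna": s.pct_rrna,
                "pct_short_pool": s.pct_short_pool,
                "pct_mirbase_of_short": s.pct_mirbase_of_short,
                "pct_other_of_filtered": s.pct_other_of_filtered,
                "pct_ensembl_of_other": s.pct_ensembl_of_other,
            }
        )
    avg: dict[str, object] = {"sample": "Average"}
    n = len(rows)
    for col in _COUNT_COLS:
        avg[col] = int(round_half_up(sum(r[col] for r in rows) / n, 0))
    for col in _PCT_COLS:
        vals = [r[col] for r in rows]
        avg[col] = None if any(v is None for v in vals) else round_half_up(
            sum(Decimal(str(v)) for v in vals) / n, 1
        )
    return pd.DataFrame(rows + [avg])
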