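"""Backsplice-junction (circRNA) detection and novelty classification.

A backsplice read is the chimera (suffix of circle end) + (prefix of circle
start).  The detector takes the two terminal anchors of each read, locates
them exactly in the genome (both strands), and calls a junction when the
anchors land on the same chromosome in reversed genomic order, the
breakpoint extension reconstructs the whole read, and the flanking
dinucleotides form a canonical strand-aware GT/AG splice signal.  Junctions
are aggregated by coordinates with distinct-read support counts, filtered at
a minimum support (default 2 reads), and classified against a circBase-style
reference: identical (chrom, start, end) -> known; exactly one shared
coordinate on the same chromosome -> new_isoform; otherwise -> novel.

This is a deliberately exact-match, desk-scale detector: anchors admit no
mismatches and ambiguous (multi-hit) anchors cause the read to be skipped
and counted, rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .preprocess import Read, revcomp

__all__ = [
    "Junction",
    "CircClassification",
    "DetectionResult",
    "detect_backsplice",
    "filter_junctions",
    "classify_vs_reference",
]


@dataclass(frozen=True)
class Junction:
    """A backsplice candidate: 0-based half-open circle span with support."""

    chrom: str
    start: int
    end: int
    strand: str
    support: int
    splice_signal: str = ""
    ambiguous_strand: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("junction start must be < end")
        if self.support < 1:
            raise ValueError("junction support must be >= 1")


@dataclass(frozen=True)
class CircClassification:
    junction: Junction
    circ_class: str  # known | new_isoform | novel
    matched_reference_id: Optional[str] = None


@dataclass
class DetectionResult:
    junctions: list[Junction]
    n_reads: int = 0
    n_skipped_short: int = 0
    n_skipped_ambiguous: int = 0
    n_unmatched: int = 0

    def __iter__(self):
        return iter(self.junctions)

    def __len__(self) -> int:
        return len(self.junctions)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    pos = haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def _locate_unique(
    genome: Mapping[str, str], needle: str
) -> tuple[Optional[tuple[str, int]], int]:
    """Locate an anchor in the genome (+ strand only); returns
    ((chrom, pos) or None, number of hits)."""
    found: list[tuple[str, int]] = []
    for chrom, seq in genome.items():
        for pos in _find_all(seq, needle):
            found.append((chrom, pos))
            if len(found) > 1:
                return None, len(found)
    if len(found) == 1:
        return found[0], 1
    return None, len(found)


def _signal(genome_seq: str, start: int, end: int) -> Optional[tuple[str, str]]:
    """Canonical backsplice signal at a circle span, strand-aware.

    Plus strand: donor GT immediately after `end`, acceptor AG immediately
    before `start`.  Minus strand: the reverse-complement pattern (AC before
    `start`, CT after `end`).  Returns (strand, 'GTAG') or None.
    """
    if start < 2 or end + 2 > len(genome_seq):
        return None
    left = genome_seq[start - 2 : start]
    right = genome_seq[end : end + 2]
    if right == "GT" and left == "AG":
        return "+", "GTAG"
    if right == "CT" and left == "AC":
        return "-", "GTAG"
    return None


def _breakpoint_candidates(
    seq: str, genome_seq: str, p1: int, p2: int, anchor_len: int
) -> list[tuple[int, int]]:
    """All splits reconstructing seq = genome[e-h:e] + genome[s:s+L-h].

    p1/p2 are the + strand positions of the first/terminal anchors.  When
    the bases flanking the two junction sides repeat, several splits are
    sequence-identical; the caller disambiguates by the splice signal.
    """
    length = len(seq)
    spans = []
    for split in range(anchor_len, length - anchor_len + 1):
        e = p1 + split
        tail = length - split
        s = p2 + anchor_len - tail
        if s < 0 or s >= e:
            continue
        if genome_seq[p1:e] == seq[:split] and genome_seq[s : s + tail] == seq[split:]:
            spans.append((s, e))
    return spans


def detect_backsplice(
    reads: Sequence[Read],
    genome: Mapping[str, str],
    anchor_len: int = 20,
) -> DetectionResult:
    """Detect backsplice junctions in reads by exact terminal-anchor mapping.

    Only reads longer than ``2 * anchor_len`` are informative; shorter reads
    are skipped and counted.  Junction support counts distinct reads; the
    output is sorted by coordinates and therefore invariant to read order.
    """
    if anchor_len < 1:
        raise ValueError("anchor_len must be >= 1")
    support: dict[tuple[str, int, int, str], set[str]] = {}
    signals: dict[tuple[str, int, int, str], tuple[str, bool]] = {}
    result = DetectionResult(junctions=[], n_reads=len(reads))
    for read in reads:
        seq_len = len(read.sequence)
        if seq_len <= 2 * anchor_len:
            result.n_skipped_short += 1
            continue
        calls = []
        ambiguous = False
        for orientation in ("+", "-"):
            seq = read.sequence if orientation == "+" else revcomp(read.sequence)
            first, f_hits = _locate_unique(genome, seq[:anchor_len])
            last, l_hits = _locate_unique(genome, seq[-anchor_len:])
            if f_hits > 1 or l_hits > 1:
                ambiguous = True
                continue
            if first is None or last is None or first[0] != last[0]:
                continue
            chrom, p1 = first
            _, p2 = last
            if p2 >= p1:  # linear order: canonical splice or contiguous, not backsplice
                continue
            # slide the breakpoint over all sequence-identical splits and
            # keep the one supported by a canonical splice signal
            for s, e in _breakpoint_candidates(seq, genome[chrom], p1, p2, anchor_len):
                sig = _signal(genome[chrom], s, e)
                if sig is None:
                    continue
                strand, motif = sig
                # read orientation must agree with the inferred signal strand
                if strand == orientation:
                    calls.append((chrom, s, e, strand, motif))
                    break
        if not calls:
            if ambiguous:
                result.n_skipped_ambiguous += 1
            else:
                result.n_unmatched += 1
            continue
        ambiguous_strand = len({c[:3] for c in calls}) == 1 and len(calls) > 1
        chrom, s, e, strand, motif = calls[0]
        if ambiguous_strand:
            strand = "+"
        key = (chrom, s, e, strand)
        support.setdefault(key, set()).add(read.id)
        signals[key] = (motif, ambiguous_strand)
    for key in sorted(support):
        chrom, s, e, strand = key
        motif, amb = signals[key]
        result.junctions.append(
            Junction(chrom, s, e, strand, len(support[key]), motif, amb)
        )
    return result


def filter_junctions(
    junctions: Iterable[Junction], min_support: int = 2
) -> list[Junction]:
    """Keep junctions confirmed by at least ``min_support`` distinct reads."""
    return [j for j in junctions if j.support >= min_support]


def classify_vs_reference(
    junction: Junction,
    circ_reference: Sequence[tuple[str, int, int, str, str]],
    slop: int = 0,
) -> CircClassification:
    """Classify a junction against a circBase-style reference.

    Reference entries are (chrom, start, end, strand, id).  Matching is
    chromosome-restricted and strand-agnostic; ``slop`` allows +-slop bp
    coordinate tolerance (default exact).
    """

    def close(a: int, b: int) -> bool:
        return abs(a - b) <= slop

    partial: Optional[str] = None
    for chrom, start, end, _strand, ref_id in circ_reference:
        if chrom != junction.chrom:
            continue
        start_match = close(start, junction.start)
        end_match = close(end, junction.end)
        if start_match and end_match:
            return CircClassification(junction, "known", ref_id)
        if (start_match or end_match) and partial is None:
            partial = ref_id
    if partial is not None:
        return CircClassification(junction, "new_isoform", partial)
    return CircClassification(junction, "novel", None)
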