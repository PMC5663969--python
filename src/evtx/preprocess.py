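"""Read-level preprocessing: quality trimming, contaminant screening, length routing.

EV libraries built from RNase-III-fragmented total RNA are dominated by short
fragments (mode 20-40 nt) and by rRNA-derived sequence.  Before any annotation,
each read is (i) trimmed from the 3' end until every 30-base sliding window of
the kept prefix exceeds a mean Phred of 15, (ii) screened against a
contaminant (rRNA/repeat) reference with an exact k-mer majority rule, and
(iii) routed by length: 12-25 nt reads go to the miRNA pool, longer reads to
the genome-annotation pool, shorter reads are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Read",
    "RoutingResult",
    "ScreenResult",
    "ContaminantIndex",
    "trim_read",
    "screen_contaminants",
    "route_by_length",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A sequenced fragment with per-base Phred qualities.

    Invariants: ``len(sequence) == len(qualities)`` and the alphabet is a
    subset of ``{A, C, G, T, N}``.
    """

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValueError(f"read {self.id}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def quality_string(self) -> str:
        """Phred+33 encoded quality string."""
        return "".join(chr(q + 33) for q in self.qualities)


def trim_read(read: Read, window: int = 30, threshold: float = 15.0) -> Read:
    """Trim a read from the 3' end to satisfy a sliding-window quality rule.

    Returns the longest prefix of *read* such that every ``window``-base
    window of the prefix (or the whole prefix, when it is shorter than
    ``window``) has mean quality strictly greater than ``threshold``.  May
    return an empty read.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = read.qualities
    n = len(q)
    if n == 0:
        return read
    # prefix sums for O(1) window means
    cum = [0]
    for v in q:
        cum.append(cum[-1] + v)

    def window_ok(i: int, j: int) -> bool:
        return (cum[j] - cum[i]) / (j - i) > threshold

    best = 0
    if n >= window:
        # first failing full window bounds the longest prefix containing
        # only passing windows
        fail = None
        for i in range(n - window + 1):
            if not window_ok(i, i + window):
                fail = i
                break
        if fail is None:
            best = n
        elif fail >= 1:
            best = fail + window - 1
    if best < window:
        # search short prefixes (whole-prefix mean rule); not monotone in
        # length, so take the longest passing one below `window`
        best = 0
        for length in range(min(window - 1, n), 0, -1):
            if window_ok(0, length):
                best = length
                break
    return Read(read.id, read.sequence[:best], read.qualities[:best])


class ContaminantIndex:
    """Exact k-mer index over contaminant sequences (both strands)."""

    def __init__(self, sequences: Iterable[tuple[str, str]], k: int = 18):
        self.k = k
        seqs = list(sequences)
        if seqs and k > min(len(s) for _, s in seqs):
            raise ValueError(f"k={k} exceeds the shortest contaminant sequence")
        kmers: set[str] = set()
        for _, seq in seqs:
            for strand_seq in (seq, revcomp(seq)):
                for i in range(len(strand_seq) - k + 1):
                    kmers.add(strand_seq[i : i + k])
        self._kmers = kmers

    def __len__(self) -> int:
        return len(self._kmers)

    def hit_fraction(self, sequence: str) -> float:
        """Fraction of the sequence's k-mers present in the index."""
        n = len(sequence) - self.k + 1
        if n <= 0 or not self._kmers:
            return 0.0
        hits = sum(1 for i in range(n) if sequence[i : i + self.k] in self._kmers)
        return hits / n


@dataclass
class ScreenResult:
    kept: list[Read]
    removed: list[Read]
    removed_fraction: float
    hit_fractions: dict[str, float] = field(default_factory=dict)


def screen_contaminants(
    reads: Sequence[Read],
    contaminants: ContaminantIndex | Iterable[tuple[str, str]],
    k: int = 18,
    min_hit_fraction: float = 0.5,
) -> ScreenResult:
    """Remove reads matching the contaminant (rRNA/repeat) reference.

    A read is removed iff at least ``min_hit_fraction`` of its k-mers occur in
    the contaminant k-mer index (both strands indexed).  With an empty
    contaminant set every read is kept.
    """
    index = (
        contaminants
        if isinstance(contaminants, ContaminantIndex)
        else ContaminantIndex(contaminants, k=k)
    )
    kept: list[Read] = []
    removed: list[Read] = []
    fractions: dict[str, float] = {}
    for read in reads:
        frac = index.hit_fraction(read.sequence)
        fractions[read.id] = frac
        (removed if frac >= min_hit_fraction else kept).append(read)
    total = len(reads)
    frac_removed = len(removed) / total if total else 0.0
    return ScreenResult(kept, removed, frac_removed, fractions)


@dataclass
class RoutingResult:
    """Length-based partition of reads into annotation pools."""

    short_pool: list[Read]
    long_pool: list[Read]
    discarded: list[Read]

    @property
    def n_short(self) -> int:
        return len(self.short_pool)

    @property
    def n_long(self) -> int:
        return len(self.long_pool)

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)


def route_by_length(
    reads: Sequence[Read], min_len: int = 12, max_len: int = 25
) -> RoutingResult:
    """Route reads of length [min_len, max_len] (inclusive) to the miRNA
    pool, longer reads to the genome pool, shorter reads to discard."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    short: list[Read] = []
    long_: list[Read] = []
    discarded: list[Read] = []
    for read in reads:
        n = len(read)
        if n < min_len:
            discarded.append(read)
        elif n <= max_len:
            short.append(read)
        else:
            long_.append(read)
    return RoutingResult(short, long_, discarded)
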