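"""Deterministic synthetic-data generator for the whole pipeline.

Emulates, at the data level only, what an RNase-III-fragmented plasma-EV
library looks like to the bioinformatics pipeline: a small random genome
carrying transcript models for a configurable biotype mixture, mature miRNA
loci, tRNA intervals, rRNA-like contaminant sequences (k-mer disjoint from
the genome so the contaminant screen can be perfect by construction),
circle loci flanked by canonical GT/AG backsplice signals, and a read set
with a short fragment-length distribution (mode ~30 nt), per-feature
coverage-uniformity control, contaminant and backsplice read fractions, and
a complete per-read truth table plus truth alignments (the repository does
not implement a genome aligner).

Everything is driven by a single integer seed: identical configuration
yields byte-identical FASTQ/SAM/truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import Alignment, ENSEMBL, FeatureModel, GTRNADB, MIRBASE
from .preprocess import Read, revcomp

__all__ = [
    "SimConfig",
    "SimConfigError",
    "ReferenceBundle",
    "CircleSpec",
    "TruthRecord",
    "SampleSim",
    "default_biotype_mix",
    "make_reference",
    "simulate_sample",
    "simulate_feature_coverage",
    "simulate_backsplice_reads",
]

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


def default_biotype_mix() -> dict[str, float]:
    """Default annotated-read biotype mixture.

    Mirrors the read-share landscape observed in plasma-EV total
    transcriptomes: ~73.25% short-noncoding (predominantly tRNA, then
    Mt_rRNA, misc_RNA and miRNA), ~24.5% protein coding, ~2.2% long
    noncoding and ~0.1% pseudogene; sums exactly to 1.
    """
    return {
        "protein_coding": 0.2449,
        "lincRNA": 0.0216,
        "processed_pseudogene": 0.0010,
        "tRNA": 0.4196,
        "Mt_rRNA": 0.1086,
        "miRNA": 0.0942,
        "Y_RNA": 0.0557,
        "SRP_7SL_RNA": 0.0382,
        "Vault_RNA": 0.0029,
        "7SK_RNA": 0.0001,
        "rRNA": 0.0060,
        "snoRNA": 0.0040,
        "snRNA": 0.0032,
    }


# (spliced length, n_exons) per biotype; unlisted biotypes default to (500, 1)
_FEATURE_PLANS: dict[str, tuple[int, int]] = {
    "protein_coding": (1800, 3),
    "lincRNA": (1000, 2),
    "processed_pseudogene": (800, 1),
    "tRNA": (72, 1),
    "Mt_rRNA": (1500, 1),
    "Mt_tRNA": (70, 1),
    "rRNA": (120, 1),
    "snoRNA": (130, 1),
    "snRNA": (150, 1),
    "misc_RNA": (200, 1),
    "Y_RNA": (100, 1),
    "SRP_7SL_RNA": (300, 1),
    "Vault_RNA": (100, 1),
    "7SK_RNA": (330, 1),
}

_INTRON = 80
_GAP = 100


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults define the study conditions."""

    seed: int = 0
    n_reads: int = 10_000
    biotype_mix: dict[str, float] = field(default_factory=default_biotype_mix)
    contaminant_fraction: float = 0.73
    circ_read_fraction: float = 0.001
    coverage_gini_target: float = 0.15
    error_rate: float = 0.0
    # fragment length: negative binomial shifted to [fragment_min, fragment_max]
    fragment_nb_size: float = 4.0
    fragment_nb_p: float = 0.15
    fragment_min: int = 12
    fragment_max: int = 200
    # reference layout
    features_per_biotype: int = 5
    n_contaminants: int = 3
    contaminant_length: int = 2000
    screen_k: int = 18
    n_circles_known: int = 4
    n_circles_isoform: int = 2
    n_circles_novel: int = 2
    n_reference_decoys: int = 3
    circ_span: int = 300
    circ_read_length: int = 50
    circ_anchor_margin: int = 20
    minus_strand_circles: bool = False

    def validate(self) -> None:
        if not self.biotype_mix:
            raise SimConfigError("biotype_mix must not be empty")
        for biotype, p in self.biotype_mix.items():
            if not (0 <= p <= 1):
                raise SimConfigError(f"mixture proportion for {biotype} outside [0,1]")
        if abs(sum(self.biotype_mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("biotype_mix must sum to 1 +- 1e-9")
        for name in ("contaminant_fraction", "circ_read_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimConfigError(f"{name} outside [0,1]")
        if not (0 <= self.coverage_gini_target < 1):
            raise SimConfigError("coverage_gini_target must be in [0,1)")
        if self.features_per_biotype < 1:
            raise SimConfigError("features_per_biotype must be >= 1")
        if self.fragment_min < 1 or self.fragment_min > self.fragment_max:
            raise SimConfigError("invalid fragment length bounds")


@dataclass(frozen=True)
class CircleSpec:
    """A simulated circle locus and its expected novelty class."""

    chrom: str
    start: int
    end: int
    strand: str
    circ_id: str
    expected_class: str  # known | new_isoform | novel


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    feature_id: str
    biotype: str
    is_contaminant: bool
    is_backsplice: bool


@dataclass
class ReferenceBundle:
    """All reference stand-ins the pipeline consumes."""

    genome: dict[str, str]
    features: list[FeatureModel]
    mirnas: list[tuple[str, str]]
    trna_intervals: list[tuple[str, int, int, str, str]]
    contaminants: list[tuple[str, str]]
    circ_reference: list[tuple[str, int, int, str, str]]
    simulated_circles: list[CircleSpec]
    screen_k: int = 18

    def validate(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature ids are not unique")
        for f in self.features:
            if f.chrom not in self.genome:
                raise ValueError(f"feature {f.id} on unknown chromosome {f.chrom}")
            if f.end > len(self.genome[f.chrom]) or f.start < 0:
                raise ValueError(f"feature {f.id} outside chromosome bounds")
        # contaminants must share no k-mer with the genome (either strand)
        genome_kmers = set()
        k = self.screen_k
        for seq in self.genome.values():
            for i in range(len(seq) - k + 1):
                genome_kmers.add(seq[i : i + k])
        for cid, seq in self.contaminants:
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - k + 1):
                    if s[i : i + k] in genome_kmers:
                        raise ValueError(
                            f"contaminant {cid} shares a {k}-mer with the genome"
                        )

    def features_by_biotype(self) -> dict[str, list[FeatureModel]]:
        out: dict[str, list[FeatureModel]] = {}
        for f in self.features:
            out.setdefault(f.biotype, []).append(f)
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_reference(config: SimConfig) -> ReferenceBundle:
    """Build the deterministic reference bundle for a configuration.

    Lays transcript models for every biotype in the mixture along a single
    synthetic chromosome, derives mature miRNA sequences and tRNA intervals
    from their loci, plants GT/AG-flanked circle loci in intergenic space,
    and generates contaminant (rRNA stand-in) sequences guaranteed to be
    k-mer disjoint from the genome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"

    features: list[FeatureModel] = []
    pos = _GAP
    for biotype in config.biotype_mix:
        plan_length, n_exons = _FEATURE_PLANS.get(biotype, (500, 1))
        for i in range(config.features_per_biotype):
            if biotype == "miRNA":
                length = int(rng.integers(18, 25))
                n_ex = 1
            else:
                length, n_ex = plan_length, n_exons
            exon_len = length // n_ex
            exons = []
            cursor = pos
            for e in range(n_ex):
                this_len = exon_len if e < n_ex - 1 else length - exon_len * (n_ex - 1)
                exons.append((cursor, cursor + this_len))
                cursor += this_len + _INTRON
            source = (
                MIRBASE
                if biotype == "miRNA"
                else GTRNADB
                if biotype == "tRNA"
                else ENSEMBL
            )
            features.append(
                FeatureModel(
                    id=f"{biotype}_{i:03d}",
                    chrom=chrom,
                    strand="+",
                    exons=tuple(exons),
                    biotype=biotype,
                    source=source,
                )
            )
            pos = exons[-1][1] + _GAP

    # circle loci in dedicated intergenic space downstream of all features
    circles: list[CircleSpec] = []
    circ_reference: list[tuple[str, int, int, str, str]] = []
    strand = "-" if config.minus_strand_circles else "+"
    ref_no = 0
    classes = (
        ["known"] * config.n_circles_known
        + ["new_isoform"] * config.n_circles_isoform
        + ["novel"] * config.n_circles_novel
    )
    for i, expected in enumerate(classes):
        pos += 50
        start, end = pos, pos + config.circ_span
        circles.append(CircleSpec(chrom, start, end, strand, f"circle_{i:02d}", expected))
        if expected == "known":
            circ_reference.append((chrom, start, end, strand, f"hsa_circ_{ref_no:04d}"))
            ref_no += 1
        elif expected == "new_isoform":
            # reference isoform sharing the start coordinate only
            circ_reference.append(
                (chrom, start, end + 137, strand, f"hsa_circ_{ref_no:04d}")
            )
            ref_no += 1
        pos = end + 50
    for _ in range(config.n_reference_decoys):
        pos += 50
        circ_reference.append(
            (chrom, pos, pos + config.circ_span, strand, f"hsa_circ_{ref_no:04d}")
        )
        ref_no += 1
        pos += config.circ_span + 50

    genome_len = pos + _GAP
    genome_seq = list(_random_seq(rng, genome_len))
    for circle in circles:
        if circle.strand == "+":
            genome_seq[circle.start - 2 : circle.start] = "AG"
            genome_seq[circle.end : circle.end + 2] = "GT"
        else:
            genome_seq[circle.start - 2 : circle.start] = "AC"
            genome_seq[circle.end : circle.end + 2] = "CT"
    genome = {chrom: "".join(genome_seq)}

    mirnas = [
        (f.id, genome[chrom][f.start : f.end])
        for f in features
        if f.source == MIRBASE
    ]
    trna_intervals = [
        (f.chrom, f.start, f.end, f.strand, f.id)
        for f in features
        if f.source == GTRNADB
    ]

    k = config.screen_k
    genome_kmers = {
        genome[chrom][i : i + k] for i in range(len(genome[chrom]) - k + 1)
    }
    contaminants: list[tuple[str, str]] = []
    for i in range(config.n_contaminants):
        for _attempt in range(100):
            seq = _random_seq(rng, config.contaminant_length)
            kmers = {seq[j : j + k] for j in range(len(seq) - k + 1)}
            rc = revcomp(seq)
            kmers |= {rc[j : j + k] for j in range(len(rc) - k + 1)}
            if kmers.isdisjoint(genome_kmers):
                contaminants.append((f"rRNA_contig_{i}", seq))
                break
        else:  # pragma: no cover - astronomically unlikely at k=18
            raise SimConfigError("could not generate a genome-disjoint contaminant")

    bundle = ReferenceBundle(
        genome=genome,
        features=features,
        mirnas=mirnas,
        trna_intervals=trna_intervals,
        contaminants=contaminants,
        circ_reference=circ_reference,
        simulated_circles=circles,
        screen_k=k,
    )
    bundle.validate()
    return bundle


def _fragment_lengths(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    raw = rng.negative_binomial(config.fragment_nb_size, config.fragment_nb_p, size=n)
    return np.clip(config.fragment_min + raw, None, config.fragment_max)


def _pick_bin(rng: np.random.Generator, n_bins: int, hot: int, w: float) -> int:
    if rng.random() < w:
        return hot
    return int(rng.integers(n_bins))


def _feature_read_interval(
    rng: np.random.Generator,
    feature: FeatureModel,
    frag_len: int,
    hot_bin: int,
    w: float,
    n_bins: int = 10,
) -> tuple[int, int]:
    """Pick a genomic (start, end) for one read of a feature.

    The target position is drawn in spliced coordinates from a
    concentration mixture (weight ``w`` on the hot bin, rest uniform) that
    realizes a chosen Gini level; the read is then placed fully inside the
    exon containing that position so its sequence is a contiguous genome
    substring.
    """
    spliced_len = feature.spliced_length
    if spliced_len >= n_bins:
        b = _pick_bin(rng, n_bins, hot_bin, w)
        base, rem = divmod(spliced_len, n_bins)
        bin_start = b * base + min(b, rem)
        bin_len = base + (1 if b < rem else 0)
        target = bin_start + int(rng.integers(bin_len))
    else:
        target = int(rng.integers(spliced_len))
    offset = 0
    for ex_start, ex_end in feature.exons:
        ex_len = ex_end - ex_start
        if target < offset + ex_len:
            pos_in_exon = target - offset
            length = min(frag_len, ex_len)
            g_start = ex_start + min(pos_in_exon, ex_len - length)
            return g_start, g_start + length
        offset += ex_len
    raise AssertionError("target position outside feature")  # pragma: no cover


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


@dataclass
class SampleSim:
    reads: list[Read]
    alignments: list[Alignment]
    truth: list[TruthRecord]


def simulate_sample(bundle: ReferenceBundle, config: SimConfig) -> SampleSim:
    """Simulate one sequenced sample: reads, truth alignments, truth table.

    Each read is, with the configured probabilities, a contaminant fragment
    (exact substring of a contaminant sequence, floored at the screen k-mer
    size), a backsplice read from a simulated circle, or a fragment of a
    transcript drawn from the biotype mixture with per-feature coverage
    concentration.  Non-contaminant linear reads get a truth alignment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    by_biotype = bundle.features_by_biotype()
    for biotype in config.biotype_mix:
        if not by_biotype.get(biotype):
            raise SimConfigError(f"mixture names biotype {biotype!r} with no features")
    mix_names = list(config.biotype_mix)
    mix_p = np.array([config.biotype_mix[b] for b in mix_names])
    mix_p = mix_p / mix_p.sum()

    n = config.n_reads
    frag_lens = _fragment_lengths(rng, config, n)
    u = rng.random(n)
    biotype_draws = rng.choice(len(mix_names), size=n, p=mix_p)
    n_bins = 10
    w = min(1.0, config.coverage_gini_target * n_bins / (n_bins - 1))
    hot_bins = {f.id: int(rng.integers(n_bins)) for f in bundle.features}
    chrom = next(iter(bundle.genome))
    genome_seq = bundle.genome[chrom]

    reads: list[Read] = []
    alignments: list[Alignment] = []
    truth: list[TruthRecord] = []
    cf = config.contaminant_fraction
    circf = config.circ_read_fraction
    margin = config.circ_anchor_margin
    for i in range(n):
        read_id = f"r{i:06d}"
        frag = int(frag_lens[i])
        if u[i] < cf and bundle.contaminants:
            cid, cseq = bundle.contaminants[int(rng.integers(len(bundle.contaminants)))]
            length = min(max(frag, bundle.screen_k), len(cseq))
            start = int(rng.integers(len(cseq) - length + 1))
            seq = cseq[start : start + length]
            truth.append(TruthRecord(read_id, cid, "", True, False))
        elif u[i] < cf + circf and bundle.simulated_circles:
            circle = bundle.simulated_circles[
                int(rng.integers(len(bundle.simulated_circles)))
            ]
            length = max(config.circ_read_length, 2 * margin + 2)
            h1 = int(rng.integers(margin, length - margin + 1))
            h1 = min(h1, circle.end - circle.start)
            tail = min(length - h1, circle.end - circle.start)
            seq = (
                genome_seq[circle.end - h1 : circle.end]
                + genome_seq[circle.start : circle.start + tail]
            )
            if circle.strand == "-":
                seq = revcomp(seq)
            truth.append(TruthRecord(read_id, circle.circ_id, "", False, True))
        else:
            biotype = mix_names[int(biotype_draws[i])]
            feats = by_biotype[biotype]
            feature = feats[int(rng.integers(len(feats)))]
            if feature.source == MIRBASE:
                g_start, g_end = feature.start, feature.end
            else:
                g_start, g_end = _feature_read_interval(
                    rng, feature, frag, hot_bins[feature.id], w, n_bins
                )
            seq = genome_seq[g_start:g_end]
            alignments.append(
                Alignment(read_id, chrom, g_start, g_end, feature.strand, mapq=60)
            )
            truth.append(TruthRecord(read_id, feature.id, biotype, False, False))
        seq = _apply_errors(rng, seq, config.error_rate)
        quals = tuple(int(q) for q in rng.integers(30, 41, size=len(seq)))
        reads.append(Read(read_id, seq, quals))
    return SampleSim(reads, alignments, truth)


def simulate_feature_coverage(
    feature: FeatureModel,
    n_reads: int,
    gini_target: float,
    seed: int,
    n_bins: int = 10,
    read_length: int = 30,
) -> list[Alignment]:
    """Simulate alignments over one feature at a controlled coverage Gini.

    Positions are drawn from a mixture putting weight ``w = target * n /
    (n-1)`` on one randomly chosen "hot" bin and the rest uniformly, whose
    population Gini equals the target exactly; sampling noise keeps the
    realized 10-bin Gini within about +-0.1 of the target for >= 500 reads.
    """
    if not (0 <= gini_target < 1):
        raise ValueError("gini_target must be in [0, 1)")
    if n_reads < 10 * n_bins:
        raise ValueError(f"n_reads must be >= {10 * n_bins} for {n_bins} bins")
    rng = np.random.default_rng(seed)
    w = min(1.0, gini_target * n_bins / (n_bins - 1))
    hot = int(rng.integers(n_bins))
    out = []
    for i in range(n_reads):
        g_start, g_end = _feature_read_interval(
            rng, feature, read_length, hot, w, n_bins
        )
        out.append(
            Alignment(f"{feature.id}_cov{i:05d}", feature.chrom, g_start, g_end,
                      feature.strand, mapq=60)
        )
    return out


def simulate_backsplice_reads(
    circ: CircleSpec | tuple[str, int, int, str, str],
    genome: dict[str, str],
    n: int,
    read_length: int = 50,
    anchor_margin: int = 20,
    seed: int = 0,
) -> list[Read]:
    """Reads spanning a circle's backsplice point.

    Each read is (suffix of circle end) + (prefix of circle start) with at
    least ``anchor_margin`` nt on both sides of the junction; minus-strand
    circles yield reverse-complemented reads.
    """
    if isinstance(circ, CircleSpec):
        chrom, start, end, strand = circ.chrom, circ.start, circ.end, circ.strand
    else:
        chrom, start, end, strand = circ[0], circ[1], circ[2], circ[3]
    span = end - start
    if span < 2 * anchor_margin:
        raise ValueError(f"circle span {span} < 2 * anchor_margin {anchor_margin}")
    if read_length < 2 * anchor_margin:
        raise ValueError(
            f"read length {read_length} < 2 * anchor_margin {anchor_margin}"
        )
    rng = np.random.default_rng(seed)
    seq = genome[chrom]
    reads = []
    for i in range(n):
        h1 = int(rng.integers(anchor_margin, read_length - anchor_margin + 1))
        h1 = min(h1, span)
        tail = min(read_length - h1, span)
        read_seq = seq[end - h1 : end] + seq[start : start + tail]
        if strand == "-":
            read_seq = revcomp(read_seq)
        reads.append(Read(f"bs_{chrom}_{start}_{end}_{i:04d}", read_seq,
                          tuple([37] * len(read_seq))))
    return reads
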