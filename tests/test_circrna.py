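"""Backsplice detection, support filtering and novelty classification."""

import numpy as np
import pytest

from evtx.circrna import (
    Junction,
    classify_vs_reference,
    detect_backsplice,
    filter_junctions,
)
from evtx.preprocess import Read
from evtx.simdata import CircleSpec, simulate_backsplice_reads


def _genome_with_circle(length=2000, start=400, end=700, strand="+", seed=0):
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    if strand == "+":
        seq[start - 2 : start] = "AG"
        seq[end : end + 2] = "GT"
    else:
        seq[start - 2 : start] = "AC"
        seq[end : end + 2] = "CT"
    return {"chr1": "".join(seq)}


def _read(seq, rid="r"):
    return Read(rid, seq, tuple([37] * len(seq)))


class TestSimulatedReadConstruction:
    def test_centered_read_is_end_suffix_plus_start_prefix(self):
        genome = _genome_with_circle(start=100, end=200)
        circle = CircleSpec("chr1", 100, 200, "+", "c", "known")
        # force the centered split by using read length 40 = 2 * margin
        reads = simulate_backsplice_reads(circle, genome, 1, read_length=40,
                                          anchor_margin=20, seed=0)
        expected = genome["chr1"][180:200] + genome["chr1"][100:120]
        assert reads[0].sequence == expected

    def test_zero_reads(self):
        genome = _genome_with_circle()
        circle = CircleSpec("chr1", 400, 700, "+", "c", "known")
        assert simulate_backsplice_reads(circle, genome, 0) == []

    def test_read_shorter_than_two_anchors_rejected(self):
        genome = _genome_with_circle()
        circle = CircleSpec("chr1", 400, 700, "+", "c", "known")
        with pytest.raises(ValueError):
            simulate_backsplice_reads(circle, genome, 1, read_length=30,
                                      anchor_margin=20)

    def test_span_too_small_rejected(self):
        genome = _genome_with_circle()
        circle = CircleSpec("chr1", 400, 430, "+", "c", "known")
        with pytest.raises(ValueError):
            simulate_backsplice_reads(circle, genome, 1, anchor_margin=20)


class TestDetection:
    def test_roundtrip_recovers_exact_coordinates(self):
        genome = _genome_with_circle(start=400, end=700)
        circle = CircleSpec("chr1", 400, 700, "+", "c", "known")
        reads = simulate_backsplice_reads(circle, genome, 5, seed=1)
        result = detect_backsplice(reads, genome)
        assert len(result.junctions) == 1
        j = result.junctions[0]
        assert (j.chrom, j.start, j.end, j.strand, j.support) == ("chr1", 400, 700, "+", 5)
        assert j.splice_signal == "GTAG"

    def test_minus_strand_circle_detected(self):
        genome = _genome_with_circle(start=400, end=700, strand="-")
        circle = CircleSpec("chr1", 400, 700, "-", "c", "known")
        reads = simulate_backsplice_reads(circle, genome, 3, seed=2)
        result = detect_backsplice(reads, genome)
        assert len(result.junctions) == 1
        assert result.junctions[0].strand == "-"

    def test_linear_read_yields_no_junction(self):
        genome = _genome_with_circle()
        reads = [_read(genome["chr1"][900:960])]
        assert detect_backsplice(reads, genome).junctions == []

    def test_forward_ordered_anchors_are_not_backsplice(self):
        # a canonical (linear) splice: upstream anchor before downstream anchor
        genome = _genome_with_circle()
        g = genome["chr1"]
        reads = [_read(g[100:130] + g[900:930])]
        assert detect_backsplice(reads, genome).junctions == []

    def test_non_canonical_flanks_rejected(self):
        genome = _genome_with_circle()
        g = genome["chr1"]
        # chimeric read in backsplice orientation but without planted GT/AG
        reads = [_read(g[1500:1530] + g[1000:1030])]
        assert detect_backsplice(reads, genome).junctions == []

    def test_ambiguous_anchor_skipped_and_counted(self):
        genome = _genome_with_circle(start=400, end=700)
        # duplicate the first anchor elsewhere to make it multi-hit
        circle = CircleSpec("chr1", 400, 700, "+", "c", "known")
        read = simulate_backsplice_reads(circle, genome, 1, seed=3)[0]
        dup = genome["chr1"] + read.sequence[:20]
        result = detect_backsplice([read], {"chr1": dup})
        assert result.junctions == [] and result.n_skipped_ambiguous == 1

    def test_detection_invariant_to_read_order(self):
        genome = _genome_with_circle(start=400, end=700)
        circle = CircleSpec("chr1", 400, 700, "+", "c", "known")
        reads = simulate_backsplice_reads(circle, genome, 4, seed=4)
        reads += [_read(genome["chr1"][900:960], "lin")]
        forward = detect_backsplice(reads, genome).junctions
        backward = detect_backsplice(list(reversed(reads)), genome).junctions
        assert forward == backward

    def test_short_reads_skipped(self):
        genome = _genome_with_circle()
        result = detect_backsplice([_read(genome["chr1"][50:90])], genome, anchor_len=20)
        assert result.n_skipped_short == 1


class TestSupportFilter:
    def _junction(self, support):
        return Junction("chr1", 10, 500, "+", support)

    @pytest.mark.parametrize("support,kept", [(1, False), (2, True), (5, True)])
    def test_min_support_boundary(self, support, kept):
        assert bool(filter_junctions([self._junction(support)])) is kept

    def test_empty_input(self):
        assert filter_junctions([]) == []


class TestClassification:
    REFERENCE = [
        ("chr1", 100, 500, "+", "hsa_circ_0001"),
        ("chr1", 2000, 2600, "+", "hsa_circ_0002"),
    ]

    def _junction(self, chrom, start, end):
        return Junction(chrom, start, end, "+", 3)

    def test_exact_coordinates_are_known(self):
        c = classify_vs_reference(self._junction("chr1", 100, 500), self.REFERENCE)
        assert c.circ_class == "known" and c.matched_reference_id == "hsa_circ_0001"

    def test_one_shared_coordinate_is_new_isoform(self):
        c = classify_vs_reference(self._junction("chr1", 100, 600), self.REFERENCE)
        assert c.circ_class == "new_isoform" and c.matched_reference_id == "hsa_circ_0001"

    def test_no_shared_coordinate_is_novel(self):
        c = classify_vs_reference(self._junction("chr2", 100, 500), self.REFERENCE)
        assert c.circ_class == "novel" and c.matched_reference_id is None

    def test_matching_is_chromosome_restricted(self):
        c = classify_vs_reference(self._junction("chr2", 100, 600), self.REFERENCE)
        assert c.circ_class == "novel"

    def test_slop_tolerance(self):
        c = classify_vs_reference(self._junction("chr1", 102, 498), self.REFERENCE,
                                  slop=2)
        assert c.circ_class == "known"

    def test_classes_partition_junctions(self):
        junctions = [
            self._junction("chr1", 100, 500),
            self._junction("chr1", 100, 700),
            self._junction("chr1", 3000, 3300),
        ]
        classes = [classify_vs_reference(j, self.REFERENCE).circ_class
                   for j in junctions]
        assert sorted(classes) == ["known", "new_isoform", "novel"]


def test_pipeline_circles_detected_and_classified(bundle, pipeline_run):
    """Every simulated circle with enough supporting reads is recovered with
    exact coordinates and its constructed novelty class."""
    report = pipeline_run["report"]
    expected = {
        (c.chrom, c.start, c.end): c.expected_class for c in bundle.simulated_circles
    }
    from collections import Counter

    from evtx.io import read_truth

    support = Counter(
        t.feature_id for t in read_truth(pipeline_run["paths"]["truth"])
        if t.is_backsplice
    )
    by_id = {c.circ_id: c for c in bundle.simulated_circles}
    min_support = pipeline_run["config"].min_circ_support
    expected_detected = {
        (c.chrom, c.start, c.end): c.expected_class
        for cid, n in support.items()
        if n >= min_support
        for c in [by_id[cid]]
    }
    observed = {
        (c.junction.chrom, c.junction.start, c.junction.end): c.circ_class
        for c in report.circ_classifications
    }
    assert observed == expected_detected
    assert set(observed) <= set(expected)
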