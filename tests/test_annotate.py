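"""miRNA matching, MAPQ filtering, overlap assignment, biotype grouping."""

import pytest

from evtx.annotate import (
    Alignment,
    ENSEMBL,
    FeatureIndex,
    FeatureModel,
    GTRNADB,
    MIRBASE,
    UNMAPPED_BIOTYPE,
    filter_mapq,
    group_biotype,
    match_mirna,
    overlap_assign,
    resolve_annotation,
)
from evtx.preprocess import Read


def _read(seq, rid="r"):
    return Read(rid, seq, tuple([30] * len(seq)))


def _feature(fid, start, end, biotype="protein_coding", source=ENSEMBL, chrom="chr1"):
    return FeatureModel(fid, chrom, "+", ((start, end),), biotype, source)


MIRNAS = [
    ("mir-b", "ACGTACGTACGTACGTACGTAC"),
    ("mir-a", "ACGTACGTACGTACGTACGTAC"),  # identical sequence, later id first lexicographically
    ("mir-c", "TTTTGGGGCCCCAAAATTTTGG"),
]


class TestMatchMirna:
    def test_exact_match(self):
        hit = match_mirna(_read("TTTTGGGGCCCCAAAATTTTGG"), MIRNAS)
        assert hit.feature_id == "mir-c" and hit.source == MIRBASE

    def test_two_substitutions_rejected_at_max_one(self):
        seq = "TATTGGGGCCCCAAAATTTAGG"  # 2 mismatches vs mir-c
        assert match_mirna(_read(seq), MIRNAS, max_mismatch=1) is None

    def test_one_substitution_accepted(self):
        seq = "TATTGGGGCCCCAAAATTTTGG"
        assert match_mirna(_read(seq), MIRNAS).feature_id == "mir-c"

    def test_3p_overhang_tolerated(self):
        # mature 22 nt + 2 untemplated 3' bases = 24 nt read
        seq = "TTTTGGGGCCCCAAAATTTTGGXX".replace("X", "A")
        assert match_mirna(_read(seq), MIRNAS).feature_id == "mir-c"

    def test_3p_trimmed_isoform_matches(self):
        assert match_mirna(_read("TTTTGGGGCCCCAAAATT"), MIRNAS).feature_id == "mir-c"

    def test_tie_broken_lexicographically_matches_exhaustive_scan(self):
        read = _read("ACGTACGTACGTACGTACGTAC")
        hit = match_mirna(read, MIRNAS)
        # exhaustive scan: all candidates with the minimum mismatch count
        exact = sorted(
            mid for mid, seq in MIRNAS if seq == read.sequence
        )
        assert hit.feature_id == exact[0] == "mir-a"

    def test_no_match_returns_none(self):
        assert match_mirna(_read("A" * 20), MIRNAS) is None


class TestMapqFilter:
    @pytest.mark.parametrize("mapq,kept", [(19, False), (20, True), (60, True)])
    def test_boundary(self, mapq, kept):
        aln = Alignment("r", "chr1", 0, 20, "+", mapq)
        assert bool(filter_mapq([aln])) is kept

    def test_order_preserved_and_empty_ok(self):
        alns = [Alignment(f"r{i}", "chr1", i, i + 10, "+", 30) for i in range(5)]
        assert filter_mapq(alns) == alns
        assert filter_mapq([]) == []


class TestOverlapAssign:
    def setup_method(self):
        self.trna = _feature("trna1", 100, 172, "tRNA", GTRNADB)
        self.gene = _feature("gene1", 150, 400)
        self.index = FeatureIndex([self.trna, self.gene])

    def test_alignment_inside_trna(self):
        aln = Alignment("r", "chr1", 110, 140, "+", 60)
        hits = overlap_assign(aln, self.index)
        assert ("trna1", 30) in hits

    def test_one_bp_overlap_is_a_hit(self):
        aln = Alignment("r", "chr1", 171, 191, "+", 60)
        hits = dict(overlap_assign(aln, self.index))
        assert hits["trna1"] == 1

    def test_no_overlap_empty(self):
        assert overlap_assign(Alignment("r", "chr1", 500, 520, "+", 60), self.index) == []

    def test_multi_exon_overlap_sums_over_exons(self):
        spliced = FeatureModel(
            "fx", "chr1", "+", ((0, 10), (20, 30)), "protein_coding", ENSEMBL
        )
        index = FeatureIndex([spliced])
        hits = dict(overlap_assign(Alignment("r", "chr1", 5, 25, "+", 60), index))
        assert hits["fx"] == 10  # 5 bp in each exon; the intron gap is excluded

    def test_stranded_mode_excludes_opposite_strand(self):
        aln = Alignment("r", "chr1", 110, 140, "-", 60)
        assert overlap_assign(aln, self.index, stranded=True) == []


class TestResolve:
    def setup_method(self):
        self.features = {
            "trna1": _feature("trna1", 100, 172, "tRNA", GTRNADB),
            "gene1": _feature("gene1", 150, 400),
            "linc1": _feature("linc1", 600, 900, "lincRNA"),
            "short_gene": _feature("short_gene", 1000, 1100),
            "long_gene": _feature("long_gene", 1000, 1500),
        }

    def test_trna_beats_protein_coding(self):
        a = resolve_annotation("r", None, [("trna1", 10)], [("gene1", 30)], self.features)
        assert a.feature_id == "trna1" and a.subcategory == "tRNA"

    def test_lone_lincrna_hit_assigned(self):
        a = resolve_annotation("r", None, [], [("linc1", 12)], self.features)
        assert a.feature_id == "linc1" and a.major_category == "long_noncoding"

    def test_largest_overlap_wins_matches_exhaustive(self):
        hits = [("gene1", 15), ("linc1", 20)]
        a = resolve_annotation("r", None, [], hits, self.features)
        brute = max(hits, key=lambda h: h[1])
        assert a.feature_id == brute[0] == "linc1"

    def test_overlap_tie_prefers_shortest_feature(self):
        hits = [("long_gene", 20), ("short_gene", 20)]
        a = resolve_annotation("r", None, [], hits, self.features)
        assert a.feature_id == "short_gene"

    def test_unannotated_returns_none(self):
        assert resolve_annotation("r", None, [], [], self.features) is None

    def test_adding_ensembl_hit_never_displaces_trna(self):
        base = resolve_annotation("r", None, [("trna1", 5)], [], self.features)
        for extra in (("gene1", 70), ("linc1", 300)):
            with_extra = resolve_annotation(
                "r", None, [("trna1", 5)], [extra], self.features
            )
            assert with_extra.feature_id == base.feature_id


class TestGroupBiotype:
    @pytest.mark.parametrize(
        "biotype,expected",
        [
            ("protein_coding", ("protein_coding", None, None)),
            ("processed_pseudogene", ("pseudogene", None, None)),
            ("lincRNA", ("long_noncoding", None, None)),
            ("Y_RNA", ("short_noncoding", "misc_RNA", "Y_RNA")),
            ("SRP_7SL_RNA", ("short_noncoding", "misc_RNA", "SRP_7SL_RNA")),
            ("Vault_RNA", ("short_noncoding", "misc_RNA", "Vault_RNA")),
            ("7SK_RNA", ("short_noncoding", "misc_RNA", "7SK_RNA")),
            ("snoRNA", ("short_noncoding", "snoRNA", None)),
            ("Mt_rRNA", ("short_noncoding", "Mt_rRNA", None)),
            ("miRNA", ("short_noncoding", "miRNA", None)),
        ],
    )
    def test_mapping_table(self, biotype, expected):
        assert tuple(group_biotype(biotype)) == expected

    def test_source_database_overrides(self):
        assert group_biotype("anything", MIRBASE).subcategory == "miRNA"
        assert group_biotype("tRNA", GTRNADB).subcategory == "tRNA"

    def test_unknown_biotype_warns_and_is_counted_separately(self):
        with pytest.warns(UserWarning):
            grouped = group_biotype("made_up_biotype")
        assert grouped.major_category == UNMAPPED_BIOTYPE


def test_assignments_match_truth_exactly(pipeline_run):
    """On error-free synthetic data every annotated read recovers its true
    source feature (100% precision and recall against the truth table)."""
    report = pipeline_run["report"]
    from evtx.io import read_truth

    truth = {
        t.read_id: t.feature_id
        for t in read_truth(pipeline_run["paths"]["truth"])
        if not t.is_contaminant and not t.is_backsplice
    }
    assigned = {a.read_id: a.feature_id for a in report.assignments}
    assert assigned == truth
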