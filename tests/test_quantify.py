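"""Count thresholds, normalization, distributions, core set, run summaries."""

import pytest

from evtx.annotate import Assignment
from evtx.quantify import (
    SampleStats,
    biotype_distribution,
    core_transcriptome,
    count_features,
    fold_change_ngs,
    normalize_per_100k,
    round_half_up,
    rpm,
    summarize_run,
)


def _assign(read_id, fid, major="protein_coding", sub=None, misc=None):
    return Assignment(read_id, fid, "Ensembl", "x", major, sub, misc)


class TestCountFeatures:
    def test_threshold_two(self):
        assignments = [_assign("r1", "A"), _assign("r2", "A"), _assign("r3", "B")]
        assert count_features(assignments, min_reads=2) == {"A": 2}

    def test_threshold_ten_excludes_nine(self):
        assignments = [_assign(f"r{i}", "A") for i in range(9)]
        assert count_features(assignments, min_reads=10) == {}
        assignments.append(_assign("r9", "A"))
        assert count_features(assignments, min_reads=10) == {"A": 10}


class TestNormalization:
    @pytest.mark.parametrize(
        "count,total,expected", [(313, 1_000_000, 313), (0, 10, 0), (5, 2_000_000, 2.5)]
    )
    def test_rpm(self, count, total, expected):
        assert rpm(count, total) == pytest.approx(expected)

    def test_rpm_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm(1, 0)

    @pytest.mark.parametrize(
        "counts,denom,expected",
        [
            ({"A": 50, "B": 50}, 100, {"A": 50_000, "B": 50_000}),
            ({"A": 10}, 10, {"A": 100_000}),
            ({"A": 3, "B": 7}, 10, {"A": 30_000, "B": 70_000}),
        ],
    )
    def test_per_100k(self, counts, denom, expected):
        assert normalize_per_100k(counts, denom) == pytest.approx(expected)

    def test_per_100k_sums_to_100k_for_complete_table(self):
        counts = {f"f{i}": i + 1 for i in range(20)}
        normalized = normalize_per_100k(counts, sum(counts.values()))
        assert sum(normalized.values()) == pytest.approx(100_000, abs=1e-6)


class TestBiotypeDistribution:
    def test_all_protein_coding(self):
        assignments = [_assign(f"r{i}", "A") for i in range(5)]
        summary = biotype_distribution(assignments, min_reads=1)
        assert summary.major_pct == {"protein_coding": 100.0}

    def test_two_category_shares(self):
        assignments = [
            _assign(f"s{i}", "S", "short_noncoding", "tRNA") for i in range(73)
        ] + [_assign(f"p{i}", "P") for i in range(27)]
        summary = biotype_distribution(assignments, min_reads=1)
        assert summary.major_pct["short_noncoding"] == pytest.approx(73)
        assert summary.major_pct["protein_coding"] == pytest.approx(27)

    def test_misc_subtype_level(self):
        assignments = (
            [_assign(f"y{i}", "Y", "short_noncoding", "misc_RNA", "Y_RNA")
             for i in range(57)]
            + [_assign(f"s{i}", "S", "short_noncoding", "misc_RNA", "SRP_7SL_RNA")
               for i in range(39)]
            + [_assign(f"v{i}", "V", "short_noncoding", "misc_RNA", "Vault_RNA")
               for i in range(3)]
            + [_assign("k0", "K", "short_noncoding", "misc_RNA", "7SK_RNA")]
        )
        summary = biotype_distribution(assignments, min_reads=1)
        assert summary.misc_subtype_pct == pytest.approx(
            {"Y_RNA": 57, "SRP_7SL_RNA": 39, "Vault_RNA": 3, "7SK_RNA": 1}
        )

    def test_each_pie_level_sums_to_100(self):
        assignments = (
            [_assign(f"p{i}", "P") for i in range(10)]
            + [_assign(f"t{i}", "T", "short_noncoding", "tRNA") for i in range(5)]
            + [_assign(f"y{i}", "Y", "short_noncoding", "misc_RNA", "Y_RNA")
               for i in range(3)]
        )
        summary = biotype_distribution(assignments, min_reads=1)
        for level in (summary.major_pct, summary.short_subcategory_pct,
                      summary.misc_subtype_pct):
            assert sum(level.values()) == pytest.approx(100, abs=0.1)

    def test_min_reads_threshold_drops_singletons(self):
        assignments = [_assign("r1", "A"), _assign("r2", "A"), _assign("r3", "B")]
        summary = biotype_distribution(assignments, min_reads=2)
        assert summary.transcript_counts == {"protein_coding": 1}
        assert summary.major_pct == {"protein_coding": 100.0}


class TestCoreTranscriptome:
    def test_intersection_and_fraction(self):
        core, fraction = core_transcriptome([{"A", "B"}, {"A", "B"}, {"A", "C"}])
        assert core == {"A"} and fraction == pytest.approx(1 / 3)

    def test_feature_in_four_of_five_not_core(self):
        sets = [{"A", "B"}] * 4 + [{"B"}]
        core, _ = core_transcriptome(sets)
        assert "A" not in core and "B" in core

    def test_requires_two_samples_and_nonempty_union(self):
        with pytest.raises(ValueError):
            core_transcriptome([{"A"}])
        with pytest.raises(ValueError):
            core_transcriptome([set(), set()])


class TestFoldChange:
    def test_printed_ngs_folds(self):
        assert fold_change_ngs(313, 19) == pytest.approx(16.47, abs=0.01)
        assert fold_change_ngs(19, 313) == pytest.approx(0.0607, abs=1e-3)
        assert fold_change_ngs(5, 5) == 1

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change_ngs(10, 0)


class TestSummarizeRun:
    def _stats(self, sid="S1", raw=1000, post=400, short=100, mir=20, ens=150):
        return SampleStats(sid, raw, post, short, mir, ens, rrna_removed=300)

    def test_reads_other_identity(self):
        s = self._stats()
        assert s.reads_other == 380 == s.post_filter_reads - s.mirbase_mapped

    def test_percentage_semantics(self):
        s = self._stats()
        assert s.pct_removed_by_filter == 60.0   # (1000-400)/1000
        assert s.pct_rrna == 30.0                # 300/1000
        assert s.pct_short_pool == 25.0          # 100/400
        assert s.pct_mirbase_of_short == 20.0    # 20/100
        assert s.pct_other_of_filtered == 95.0   # 380/400
        assert s.pct_ensembl_of_other == pytest.approx(39.5)  # 150/380

    def test_single_sample_average_equals_sample(self):
        table = summarize_run([self._stats()])
        sample_row = table.iloc[0]
        avg = table.iloc[-1]
        for col in table.columns[1:]:
            assert avg[col] == sample_row[col]

    def test_average_of_percentages_not_ratio_of_averages(self):
        a = self._stats("A", raw=1000, post=100)   # 90.0% removed
        b = self._stats("B", raw=100, post=80)     # 20.0% removed
        table = summarize_run([a, b])
        avg = table[table["sample"] == "Average"].iloc[0]
        assert avg["pct_removed_by_filter"] == pytest.approx(55.0)
        # ratio-of-averages would give 100*(1100-180)/1100 = 83.6 instead

    def test_count_average_rounds_half_up(self):
        a = self._stats("A", raw=3)
        b = self._stats("B", raw=4)
        table = summarize_run([a, b])
        assert table[table["sample"] == "Average"].iloc[0]["raw_reads"] == 4  # 3.5 up


def test_round_half_up_convention():
    assert round_half_up(8.35, 1) == 8.4
    assert round_half_up(372793.6, 0) == 372794
    assert round_half_up(2.25, 1) == 2.3
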