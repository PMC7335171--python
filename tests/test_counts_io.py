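"""Count-table I/O, interval counting, density and fold-change rules."""

import numpy as np
import pandas as pd
import pytest

from nmdquant import (
    FeatureCountTable,
    GenomicInterval,
    SampleSheet,
    compute_density,
    count_feature_reads,
    filter_low_expression,
    fold_change,
    read_bed,
    read_count_table,
    write_bed,
    write_count_table,
)
from nmdquant.counts_io import CountTableError


class TestCountTable:
    def test_round_trip(self, two_gene_table, tmp_path):
        path = tmp_path / "counts.tsv"
        write_count_table(two_gene_table, path)
        back = read_count_table(path)
        expected = two_gene_table.frame.sort_values(["gene_id", "feature_type"])
        pd.testing.assert_frame_equal(
            back.frame.reset_index(drop=True), expected.reset_index(drop=True)
        )

    def test_negative_count_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene_id\tfeature_type\tlength_bp\ts1\n"
            "A\texon\t100\t5\n"
            "A\tintron\t100\t-3\n"
        )
        with pytest.raises(CountTableError, match="negative count"):
            read_count_table(path)

    def test_duplicate_key_rejected(self):
        df = pd.DataFrame(
            {
                "gene_id": ["A", "A"],
                "feature_type": ["exon", "exon"],
                "length_bp": [100, 100],
                "s1": [1, 2],
            }
        )
        with pytest.raises(CountTableError, match="duplicate"):
            FeatureCountTable(df)

    def test_zero_length_rejected(self):
        df = pd.DataFrame(
            {"gene_id": ["A"], "feature_type": ["exon"], "length_bp": [0], "s1": [1]}
        )
        with pytest.raises(CountTableError, match="length_bp"):
            FeatureCountTable(df)


class TestSampleSheet:
    def test_duplicate_sample_rejected(self):
        with pytest.raises(CountTableError, match="duplicate"):
            SampleSheet(pd.DataFrame({"sample_id": ["a", "a"], "group": ["x", "y"]}))

    def test_unknown_group_errors(self, two_group_sheet):
        with pytest.raises(CountTableError, match="unknown"):
            two_group_sheet.samples_in_group("nope")


class TestIntervalCounting:
    FEATURES = [
        GenomicInterval("chr1", 0, 100, "g1", "exon"),
        GenomicInterval("chr1", 100, 200, "g1", "intron"),
    ]

    def counts_of(self, table, gene, ftype):
        sub = table.frame.query("gene_id == @gene and feature_type == @ftype")
        return int(sub[table.sample_ids[0]].iloc[0])

    def test_read_inside_exon(self):
        table = count_feature_reads(
            [GenomicInterval("chr1", 50, 60)], self.FEATURES
        )
        assert self.counts_of(table, "g1", "exon") == 1
        assert self.counts_of(table, "g1", "intron") == 0

    def test_junction_read_goes_to_exon(self):
        table = count_feature_reads(
            [GenomicInterval("chr1", 95, 105)], self.FEATURES
        )
        assert self.counts_of(table, "g1", "exon") == 1
        assert self.counts_of(table, "g1", "intron") == 0

    def test_empty_features_give_empty_table(self):
        table = count_feature_reads([GenomicInterval("chr1", 0, 10)], [])
        assert table.frame.empty

    def test_matches_all_pairs_oracle(self):
        """1000 random reads vs random features == naive all-pairs scan."""
        rng = np.random.default_rng(42)
        features = []
        for g in range(15):
            pos = 0
            for k in range(rng.integers(1, 4)):
                exon_len, intron_len = rng.integers(50, 300, 2)
                start = g * 5000 + pos
                features.append(
                    GenomicInterval("chr1", start, start + exon_len, f"g{g}", "exon")
                )
                features.append(
                    GenomicInterval(
                        "chr1", start + exon_len, start + exon_len + intron_len,
                        f"g{g}", "intron",
                    )
                )
                pos += exon_len + intron_len + rng.integers(0, 100)
        reads = []
        for _ in range(1000):
            start = int(rng.integers(0, 15 * 5000))
            reads.append(GenomicInterval("chr1", start, start + 50))

        table = count_feature_reads(reads, features)

        # oracle: all-pairs overlap scan with the same exon-priority rule
        expected: dict[tuple[str, str], int] = {}
        for read in reads:
            exon_hits, intron_hits = set(), set()
            for f in features:
                overlap = min(read.end, f.end) - max(read.start, f.start)
                if f.chrom == read.chrom and overlap >= 1:
                    (exon_hits if f.feature_type == "exon" else intron_hits).add(f.gene_id)
            for g in exon_hits:
                expected[(g, "exon")] = expected.get((g, "exon"), 0) + 1
            for g in intron_hits - exon_hits:
                expected[(g, "intron")] = expected.get((g, "intron"), 0) + 1

        sample = table.sample_ids[0]
        for _, row in table.frame.iterrows():
            key = (row["gene_id"], row["feature_type"])
            assert row[sample] == expected.get(key, 0), key

    def test_bed_round_trip(self, tmp_path):
        path = tmp_path / "f.bed"
        write_bed(self.FEATURES, path)
        back = read_bed(path)
        assert [(iv.chrom, iv.start, iv.end, iv.gene_id) for iv in back] == [
            ("chr1", 0, 100, "g1"),
            ("chr1", 100, 200, "g1"),
        ]


class TestFilterLowExpression:
    @staticmethod
    def _table(counts_by_sample):
        n = len(counts_by_sample[0])
        df = pd.DataFrame(
            {
                "gene_id": ["A"] * 2,
                "feature_type": ["exon", "intron"],
                "length_bp": [100, 100],
            }
        )
        for i, col in enumerate(counts_by_sample):
            df[f"s{i}"] = col
        return FeatureCountTable(df)

    def test_below_threshold_excluded(self):
        # gene totals per sample 0,0,1 -> mean 1/3 < 1
        t = self._table([[0, 0], [0, 0], [1, 0]])
        assert filter_low_expression(t).frame.empty

    def test_boundary_retained(self):
        # totals 0,1,2 -> mean exactly 1: strict "<1" exclusion keeps it
        t = self._table([[0, 0], [1, 0], [2, 0]])
        assert set(filter_low_expression(t).gene_ids) == {"A"}

    def test_zero_threshold_is_identity(self, two_gene_table):
        out = filter_low_expression(two_gene_table, 0.0)
        pd.testing.assert_frame_equal(out.frame, two_gene_table.frame)

    def test_idempotent(self, two_gene_table):
        once = filter_low_expression(two_gene_table, 30.0)
        twice = filter_low_expression(once, 30.0)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_negative_threshold_errors(self, two_gene_table):
        with pytest.raises(CountTableError):
            filter_low_expression(two_gene_table, -1.0)


class TestDensity:
    def test_rpm_definitions(self, two_gene_table, two_group_sheet):
        d = compute_density(two_gene_table, two_group_sheet)
        row = d.query("gene_id == 'A' and feature_type == 'exon' and sample_id == 's1'")
        assert row["rpm"].iloc[0] == pytest.approx(10.0)  # 10 reads / 1e6
        assert row["density_per_kb"].iloc[0] == pytest.approx(10.0)  # 1 kb feature

    def test_rpm_scales_with_library(self, two_gene_table):
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "group": ["case", "control"],
                    "library_size": [2_000_000, 1_000_000],
                }
            )
        )
        d = compute_density(two_gene_table, sheet)
        row = d.query("gene_id == 'A' and feature_type == 'exon' and sample_id == 's1'")
        assert row["rpm"].iloc[0] == pytest.approx(5.0)

    def test_missing_library_falls_back_with_warning(self, two_gene_table):
        sheet = SampleSheet(
            pd.DataFrame({"sample_id": ["s1", "s2"], "group": ["case", "control"]})
        )
        with pytest.warns(UserWarning, match="library_size"):
            d = compute_density(two_gene_table, sheet)
        total_s1 = two_gene_table.frame["s1"].sum()
        row = d.query("gene_id == 'B' and feature_type == 'exon' and sample_id == 's1'")
        assert row["rpm"].iloc[0] == pytest.approx(100 * 1e6 / total_s1)

    def test_rpm_conservation(self, two_gene_table, two_group_sheet):
        """Per-sample RPM sums to 1e6 * assigned/library."""
        d = compute_density(two_gene_table, two_group_sheet)
        for sid in ("s1", "s2"):
            sub = d[d["sample_id"] == sid]
            assigned = two_gene_table.frame[sid].sum()
            assert sub["rpm"].sum() == pytest.approx(1e6 * assigned / 1_000_000)


class TestFoldChange:
    def _density(self, case_vals, control_vals, feature="exon"):
        n = len(case_vals)
        rows = []
        for i, (c, k) in enumerate(zip(case_vals, control_vals)):
            rows.append(
                {"gene_id": f"g{i}", "feature_type": feature, "sample_id": "s_case",
                 "rpm": c, "density_per_kb": c}
            )
            rows.append(
                {"gene_id": f"g{i}", "feature_type": feature, "sample_id": "s_ctrl",
                 "rpm": k, "density_per_kb": k}
            )
        sheet = SampleSheet(
            pd.DataFrame({"sample_id": ["s_case", "s_ctrl"], "group": ["case", "control"]})
        )
        return pd.DataFrame(rows), sheet

    def test_zero_vs_zero_is_zero(self):
        d, sheet = self._density([0.0], [0.0])
        fc = fold_change(d, sheet, "case", "control")
        assert fc["log2fc"].iloc[0] == 0.0

    def test_pseudo_count_arithmetic(self):
        d, sheet = self._density([0.9], [0.1])
        fc = fold_change(d, sheet, "case", "control", pseudo=0.1)
        assert fc["log2fc"].iloc[0] == pytest.approx(np.log2(5.0))

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(7)
        d, sheet = self._density(rng.uniform(0, 50, 20), rng.uniform(0, 50, 20))
        fwd = fold_change(d, sheet, "case", "control")
        rev = fold_change(d, sheet, "control", "case")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)

    def test_unknown_group_errors(self):
        d, sheet = self._density([1.0], [1.0])
        with pytest.raises(CountTableError):
            fold_change(d, sheet, "case", "mystery")

    def test_intron_feature_uses_density_per_kb(self, two_gene_table, two_group_sheet):
        d = compute_density(two_gene_table, two_group_sheet)
        fc = fold_change(d, two_group_sheet, "case", "control", feature="intron")
        # gene A: intron 2 kb, counts 2 vs 3 -> densities 1.0 vs 1.5 per kb
        a = fc.set_index("gene_id").loc["A", "log2fc"]
        assert a == pytest.approx(np.log2(1.1 / 1.6))
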