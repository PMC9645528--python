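"""Fractional feature counting and normalization statistics."""

import numpy as np
import pandas as pd
import pytest

from mirproc.intervals import GenomicInterval
from mirproc.quantify import (AlignedRead, CountTable, base_mean_and_lfc,
                              count_features, cpm_normalize, size_factors)

FEAT = [
    ("mirA", GenomicInterval("chr1", 100, 122, "+")),
    ("mirB", GenomicInterval("chr1", 300, 322, "+")),
    ("mirC", GenomicInterval("chr1", 500, 522, "-")),
]


def _read(start, end, strand="+", n_hits=1, alns=None, rid="r", chrom="chr1"):
    alns = alns or [GenomicInterval(chrom, start, end, strand)]
    return AlignedRead(rid, "s1", end - start, alns, n_hits)


def _oracle(reads_by_sample, features, min_overlap=15, length_range=(19, 25)):
    """All-pairs overlap scan, independent of the tree-based implementation."""
    counts = {name: {s: 0.0 for s in reads_by_sample} for name, _ in features}
    for sample, reads in reads_by_sample.items():
        for read in reads:
            if not (length_range[0] <= read.length <= length_range[1]):
                continue
            for aln in read.alignments:
                hits = [
                    name for name, fiv in features
                    if fiv.chrom == aln.chrom and fiv.strand == aln.strand
                    and min(fiv.end, aln.end) - max(fiv.start, aln.start) >= min_overlap
                ]
                for name in hits:
                    counts[name][sample] += 1.0 / (read.n_hits * len(hits))
    return counts


class TestCountFeatures:
    def test_unique_read_counts_one(self):
        t = count_features({"s1": [_read(100, 122)]}, FEAT)
        assert t.counts.loc["mirA", "s1"] == pytest.approx(1.0)

    def test_two_alignments_half_each(self):
        alns = [GenomicInterval("chr1", 100, 122, "+"),
                GenomicInterval("chr1", 300, 322, "+")]
        r = AlignedRead("r", "s1", 22, alns, 2)
        t = count_features({"s1": [r]}, FEAT)
        assert t.counts.loc["mirA", "s1"] == pytest.approx(0.5)
        assert t.counts.loc["mirB", "s1"] == pytest.approx(0.5)

    def test_overlap_below_minimum_ignored(self):
        # 22-nt read overlapping mirA by only 14 nt
        t = count_features({"s1": [_read(108, 130)]}, FEAT)
        assert t.counts["s1"].sum() == 0.0

    def test_antisense_not_counted(self):
        t = count_features({"s1": [_read(100, 122, strand="-")]}, FEAT)
        assert t.counts.loc["mirA", "s1"] == 0.0
        t2 = count_features({"s1": [_read(500, 522, strand="-")]}, FEAT)
        assert t2.counts.loc["mirC", "s1"] == pytest.approx(1.0)

    def test_length_filter(self):
        t = count_features({"s1": [_read(100, 118)]}, FEAT)  # 18 nt
        assert t.counts["s1"].sum() == 0.0

    def test_matches_brute_force_oracle(self):
        """500 random reads x 20 random features, tree vs all-pairs scan."""
        rng = np.random.default_rng(17)
        features = []
        for i in range(20):
            s = int(rng.integers(0, 5000))
            features.append((f"f{i}", GenomicInterval(
                "chr1", s, s + int(rng.integers(20, 40)),
                "+" if rng.random() < 0.5 else "-")))
        reads = []
        for j in range(500):
            n_aln = int(rng.integers(1, 4))
            alns = []
            length = int(rng.integers(17, 28))
            for _ in range(n_aln):
                s = int(rng.integers(0, 5000))
                alns.append(GenomicInterval(
                    "chr1", s, s + length, "+" if rng.random() < 0.5 else "-"))
            reads.append(AlignedRead(f"r{j}", "s1", length, alns, n_aln))
        by_sample = {"s1": reads}
        t = count_features(by_sample, features)
        oracle = _oracle(by_sample, features)
        for name, _ in features:
            assert t.counts.loc[name, "s1"] == pytest.approx(
                oracle[name]["s1"], abs=1e-12)

    def test_weight_conservation(self):
        """A read contributes total mass <= 1, with equality when every
        alignment hits at least one feature."""
        alns = [GenomicInterval("chr1", 100, 122, "+"),
                GenomicInterval("chr1", 300, 322, "+")]
        r = AlignedRead("r", "s1", 22, alns, 2)
        t = count_features({"s1": [r]}, FEAT)
        assert t.counts["s1"].sum() == pytest.approx(1.0)
        # one alignment in a feature desert: mass drops below 1
        alns2 = [GenomicInterval("chr1", 100, 122, "+"),
                 GenomicInterval("chr1", 4000, 4022, "+")]
        r2 = AlignedRead("r", "s1", 22, alns2, 2)
        t2 = count_features({"s1": [r2]}, FEAT)
        assert t2.counts["s1"].sum() == pytest.approx(0.5)

    def test_sample_order_permutes_columns_only(self):
        reads = {"a": [_read(100, 122)], "b": [_read(300, 322)]}
        t1 = count_features(reads, FEAT)
        t2 = count_features({k: reads[k] for k in ["b", "a"]}, FEAT)
        pd.testing.assert_frame_equal(t1.counts, t2.counts[["a", "b"]])

    def test_empty_annotation_warns(self):
        with pytest.warns(UserWarning, match="empty annotation"):
            t = count_features({"s1": [_read(100, 122)]}, [])
        assert t.counts.empty


class TestSizeFactors:
    def test_identical_samples(self):
        c = pd.DataFrame({"a": [10.0, 5.0, 2.0], "b": [10.0, 5.0, 2.0]})
        sf = size_factors(c)
        assert sf["a"] == pytest.approx(1.0)
        assert sf["b"] == pytest.approx(1.0)

    def test_doubled_sample(self):
        c = pd.DataFrame({"a": [10.0, 5.0, 2.0], "b": [20.0, 10.0, 4.0]})
        sf = size_factors(c)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_median_of_ratios_oracle(self):
        """3x2 toy matrix against a hand-computed median-of-ratios."""
        c = pd.DataFrame({"a": [4.0, 9.0, 25.0], "b": [1.0, 4.0, 4.0]})
        gm = np.sqrt(c["a"] * c["b"])                # per-feature geometric mean
        expected_a = np.median(c["a"] / gm)
        expected_b = np.median(c["b"] / gm)
        sf = size_factors(c)
        assert sf["a"] == pytest.approx(expected_a)
        assert sf["b"] == pytest.approx(expected_b)

    def test_fallback_total_count(self):
        c = pd.DataFrame({"a": [10.0, 0.0], "b": [0.0, 30.0]})
        with pytest.warns(UserWarning, match="total-count"):
            sf = size_factors(c)
        assert sf["b"] / sf["a"] == pytest.approx(3.0)


class TestBaseMeanLfc:
    def _table(self, counts):
        lt = pd.DataFrame(1.0, index=range(19, 26), columns=counts.columns)
        return CountTable(counts=counts, length_totals=lt)

    def test_identical_groups_zero_lfc(self):
        c = pd.DataFrame({"a1": [8.0, 2.0], "b1": [8.0, 2.0]},
                         index=["f1", "f2"])
        stats = base_mean_and_lfc(self._table(c), (["a1"], ["b1"]))
        assert (stats["log2fc"] == 0).all()

    def test_lfc_arithmetic(self):
        c = pd.DataFrame({"a1": [8.0], "b1": [2.0]}, index=["f1"])
        t = self._table(c)
        t.size_factors = pd.Series({"a1": 1.0, "b1": 1.0})
        stats = base_mean_and_lfc(t, (["a1"], ["b1"]), pseudocount=0.0)
        assert stats.loc["f1", "log2fc"] == pytest.approx(-2.0)
        assert stats.loc["f1", "base_mean"] == pytest.approx(5.0)

    def test_empty_group_rejected(self):
        c = pd.DataFrame({"a1": [8.0]}, index=["f1"])
        with pytest.raises(ValueError):
            base_mean_and_lfc(self._table(c), ([], ["a1"]))


class TestCpm:
    def _table(self):
        counts = pd.DataFrame({"s1": [3.0, 1.0]}, index=["f1", "f2"])
        lt = pd.DataFrame(0.0, index=range(19, 26), columns=["s1"])
        lt.loc[22, "s1"] = 8.0   # 21-23 nt reads
        lt.loc[19, "s1"] = 2.0   # counted but outside 21-23
        return CountTable(counts=counts, length_totals=lt)

    def test_denominator_choice(self):
        t = self._table()
        all_cpm = cpm_normalize(t, "all_counted")
        assert all_cpm.loc["f1", "s1"] == pytest.approx(3.0 / 10.0 * 1e6)
        sub_cpm = cpm_normalize(t, "length_21_23")
        assert sub_cpm.loc["f1", "s1"] == pytest.approx(3.0 / 8.0 * 1e6)

    def test_linearity(self):
        t = self._table()
        doubled = CountTable(counts=t.counts * 2, length_totals=t.length_totals * 2)
        pd.testing.assert_frame_equal(cpm_normalize(t), cpm_normalize(doubled))

    def test_zero_denominator_rejected(self):
        t = self._table()
        t.length_totals["s1"] = 0.0
        with pytest.raises(ValueError):
            cpm_normalize(t)
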