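"""Cleavage-point redefinition, density difference matrices, shift recovery."""

import numpy as np
import pandas as pd
import pytest

from mirproc.fidelity import (collect_end_profiles, fidelity_matrix,
                              recovered_shift, redefine_cp, select_and_order)
from mirproc.intervals import GenomicInterval
from mirproc.quantify import AlignedRead

W = 15  # window half-width; vectors span CP-15..CP+15


def _window(offset_counts, n_rep=1):
    """Build (n_rep, 31) windows from {offset: count} (same in each rep)."""
    v = np.zeros((n_rep, 2 * W + 1))
    for off, c in offset_counts.items():
        v[:, W + off] = c
    return v


class TestRedefineCp:
    def test_no_reads_keeps_canonical(self):
        assert redefine_cp(np.zeros((3, 31))) == 0

    def test_shift_beyond_seven_keeps_canonical(self):
        assert redefine_cp(_window({9: 10.0})) == 0
        assert redefine_cp(_window({-8: 10.0})) == 0
        assert redefine_cp(_window({7: 10.0})) == 7

    def test_tie_keeps_canonical(self):
        assert redefine_cp(_window({0: 5.0, 2: 5.0})) == 0
        assert redefine_cp(_window({1: 5.0, 3: 5.0})) == 0

    def test_clear_maximum_moves_cp(self):
        """Replicate medians (..., 3, 10, 3, ...) with the 10 at +1."""
        w = _window({0: 3.0, 1: 10.0, 2: 3.0}, n_rep=3)
        assert redefine_cp(w) == 1

    def test_median_across_replicates(self):
        # reps disagree; median decides: counts at +2 are (0, 9, 9) -> med 9,
        # at 0 are (8, 8, 8) -> med 8
        w = np.zeros((3, 31))
        w[:, W] = 8.0
        w[1:, W + 2] = 9.0
        assert redefine_cp(w) == 2
        # even replicate count: median = mean of central values
        w2 = np.zeros((2, 31))
        w2[:, W] = 4.0
        w2[0, W + 1] = 2.0
        w2[1, W + 1] = 8.0   # median at +1 = 5 > 4
        assert redefine_cp(w2) == 1


class TestFidelityMatrix:
    def _profiles(self, mut_spec, wt_spec):
        key = ("mirX-3p", "start_at_3p5CP")
        return ({key: _window(mut_spec, 2)}, {key: _window(wt_spec, 2)})

    def test_mutant_equals_wt_gives_zero_rows(self):
        mut, wt = self._profiles({0: 10.0, 1: 5.0}, {0: 10.0, 1: 5.0})
        diff = fidelity_matrix(mut, wt)
        row = diff.iloc[0][list(range(-5, 6))].astype(float)
        assert np.allclose(row, 0.0)

    def test_diff_rows_sum_to_zero(self):
        mut, wt = self._profiles({0: 3.0, 2: 9.0}, {0: 10.0, -1: 2.0})
        diff = fidelity_matrix(mut, wt)
        assert abs(diff.iloc[0][list(range(-5, 6))].sum()) < 1e-9

    def test_planted_shift_appears_in_diff(self):
        mut, wt = self._profiles({0: 2.0, 2: 8.0}, {0: 10.0})
        diff = fidelity_matrix(mut, wt)
        row = diff.iloc[0]
        assert row[2] == pytest.approx(0.8)
        assert row[0] == pytest.approx(-0.8)
        assert recovered_shift(row) == 2

    def test_zero_group_flagged(self):
        mut, wt = self._profiles({}, {0: 10.0})
        diff = fidelity_matrix(mut, wt)
        assert bool(diff.iloc[0]["flagged"])

    def test_cp_redefined_from_wt_only(self):
        """Permuting / altering mutant data never changes the new CP."""
        key = ("m", "start_at_3p5CP")
        wt = {key: _window({3: 9.0, 0: 1.0}, 2)}
        for mut_spec in ({0: 50.0}, {-4: 7.0}, {3: 1.0}):
            diff = fidelity_matrix({key: _window(mut_spec, 2)}, wt)
            assert diff.iloc[0]["new_cp_offset"] == 3


class TestSelectAndOrder:
    def _diff(self, center_vals):
        cols = list(range(-5, 6)) + ["new_cp_offset", "flagged"]
        rows = []
        for v in center_vals:
            row = [0.0] * 11 + [0, False]
            row[5] = v
            rows.append(row)
        idx = pd.MultiIndex.from_tuples(
            [(f"m{i}", "start_at_3p5CP") for i in range(len(center_vals))],
            names=["mirna", "end_kind"])
        return pd.DataFrame(rows, index=idx, columns=cols)

    def test_selects_by_absolute_central_diff(self):
        diff = self._diff([0.9, -0.5, 0.1])
        top = select_and_order(diff, k=2)
        assert [i[0] for i in top.index] == ["m0", "m1"]

    def test_orders_by_signed_value_in_ordering_dataset(self):
        diff = self._diff([0.5, -0.9, 0.1])
        order = self._diff([-1.0, 1.0, 0.0])
        top = select_and_order(diff, order, k=2)
        # picked: m1 (|−0.9|), m0 (0.5); ordered by signed order diff: m1 first
        assert [i[0] for i in top.index] == ["m1", "m0"]

    def test_k_exceeding_rows_warns_and_returns_all(self):
        diff = self._diff([0.5, 0.1])
        with pytest.warns(UserWarning):
            top = select_and_order(diff, k=50)
        assert len(top) == 2

    def test_selection_invariant_under_shuffling(self):
        diff = self._diff([0.9, -0.5, 0.1, 0.3])
        top1 = select_and_order(diff, k=3)
        top2 = select_and_order(diff.iloc[[2, 0, 3, 1]], k=3)
        assert list(top1.index) == list(top2.index)


class TestRecoveredShift:
    def test_all_zero_signalled(self):
        with pytest.raises(ValueError):
            recovered_shift(np.zeros(11))

    def test_tie_prefers_smallest_offset(self):
        row = np.zeros(11)
        row[5 + 3] = 0.4
        row[5 - 2] = 0.4
        row[5] = -0.8
        assert recovered_shift(row) == -2


class TestCollectEndProfiles:
    def _reads(self, h, offsets_3p, rep="r1"):
        reads = []
        for i, off in enumerate(offsets_3p):
            lo = h.cp_3p5 + off
            gs, ge = h.local_to_genomic(lo, min(len(h.sequence), lo + 21))
            iv = GenomicInterval(h.interval.chrom, gs, ge, h.interval.strand)
            reads.append(AlignedRead(f"{rep}_{i}", rep, ge - gs, [iv], 1))
        return reads

    def test_reads_at_canonical_cp_fill_center_only(self, toy_hairpin):
        h = toy_hairpin
        profiles = collect_end_profiles([self._reads(h, [0] * 20)], [h])
        w = profiles[("toy-mir-3p", "start_at_3p5CP")][0]
        assert w[W] == 20
        assert w.sum() == 20

    def test_read_outside_window_not_tallied(self, toy_hairpin):
        h = toy_hairpin
        # start 16 nt upstream of the CP: outside the +/-15 window
        lo = h.cp_3p5 - 16
        gs, ge = h.local_to_genomic(lo, lo + 21)
        read = AlignedRead("x", "r1", 21,
                           [GenomicInterval("chrT", gs, ge, "+")], 1)
        profiles = collect_end_profiles([[read]], [h])
        assert profiles[("toy-mir-3p", "start_at_3p5CP")][0].sum() == 0

    def test_offset_mixture_ratio(self, toy_hairpin):
        """Planted offsets {0: 0.7, +2: 0.3}: tally ratio within 3 binomial SD."""
        h = toy_hairpin
        rng = np.random.default_rng(21)
        n = 4000
        offs = rng.choice([0, 2], p=[0.7, 0.3], size=n)
        profiles = collect_end_profiles([self._reads(h, offs)], [h])
        w = profiles[("toy-mir-3p", "start_at_3p5CP")][0]
        frac = w[W] / n
        assert abs(frac - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / n)
        assert w[W] + w[W + 2] == n

    def test_minus_strand_orientation(self):
        """Offsets increase into the mature miRNA on the minus strand too."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGU"), size=60))
        from mirproc.hairpin import HairpinLocus
        h = HairpinLocus("neg", GenomicInterval("chrT", 2000, 2060, "-"),
                         seq, mature5p=(1, 22), mature3p=(39, 60))
        # a 3p read starting at local cp+2 (= shortened mature)
        gs, ge = h.local_to_genomic(h.cp_3p5 + 2, 60)
        read = AlignedRead("x", "r1", ge - gs,
                           [GenomicInterval("chrT", gs, ge, "-")], 1)
        profiles = collect_end_profiles([[read]], [h])
        w = profiles[("neg-3p", "start_at_3p5CP")][0]
        assert w[W + 2] == 1
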