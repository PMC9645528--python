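"""Four-step small RNA cluster calling, replicate intersection, annotation."""

import numpy as np
import pytest

from mirproc.clusters import (Cluster, annotate_clusters,
                              call_clusters_replicate, consolidate_genotype)
from mirproc.intervals import GenomicInterval
from mirproc.quantify import AlignedRead


def _read(start, length=22, n_hits=1, chrom="chr1", rid=None):
    iv = GenomicInterval(chrom, start, start + length, "+")
    return AlignedRead(rid or f"r{start}", "s", length, [iv], n_hits)


def oracle_clusters(alignments, denom, rpm_min=3.0, join_dist=50):
    """Fixed-point pairwise collapse/merge, independent of sweep order."""
    regions = [[s, e, w] for s, e, w in alignments]

    def merge_pass(regs, max_gap):
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                a, b = regs[i], regs[j]
                gap = max(a[0], b[0]) - min(a[1], b[1])
                if gap <= max_gap:
                    merged = [min(a[0], b[0]), max(a[1], b[1]), a[2] + b[2]]
                    return [r for k, r in enumerate(regs)
                            if k not in (i, j)] + [merged]
        return None

    while (nxt := merge_pass(regions, -1)) is not None:
        regions = nxt
    regions = [r for r in regions if 1e6 * r[2] / denom >= rpm_min]
    while (nxt := merge_pass(regions, join_dist)) is not None:
        regions = nxt
    return sorted((s, e, round(w, 9)) for s, e, w in regions)


class TestCallClusters:
    def test_two_overlapping_reads_kept(self):
        """Two overlapping 22-nt unique alignments in a 1e5-read replicate:
        one region, weight 2, RPM 20, retained."""
        reads = [_read(100, rid="a"), _read(110, rid="b")]
        out = call_clusters_replicate(reads, total_weight=1e5)
        assert len(out) == 1
        assert out[0].weight == pytest.approx(2.0)
        assert out[0].rpm == pytest.approx(20.0)

    def test_below_rpm_threshold_discarded(self):
        # single region with RPM 2.9 < 3
        reads = [_read(100, rid=f"a{i}") for i in range(29)]
        out = call_clusters_replicate(reads, total_weight=1e7)
        assert out == []

    def test_join_distance_inclusive_at_50(self):
        reads = [_read(100, rid="a"), _read(172, rid="b")]  # gap exactly 50
        out = call_clusters_replicate(reads, total_weight=1e5)
        assert len(out) == 1
        reads = [_read(100, rid="a"), _read(173, rid="b")]  # gap 51
        out = call_clusters_replicate(reads, total_weight=1e5)
        assert len(out) == 2

    def test_length_selection(self):
        reads = [_read(100, length=25, rid="a")]  # outside 21-23
        assert call_clusters_replicate(reads, total_weight=1e3) == []

    def test_fractional_weighting(self):
        reads = [_read(100, n_hits=2, rid="a")]
        out = call_clusters_replicate(reads, rpm_min=0.0, total_weight=100)
        assert out[0].weight == pytest.approx(0.5)

    def test_matches_brute_force_oracle_random(self):
        """30 random reads over 3 seeded source regions equal the exhaustive
        collapse/merge oracle, across 100 random instances."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sources = rng.integers(0, 2000, size=3)
            reads, alns = [], []
            for i in range(30):
                src = int(sources[rng.integers(0, 3)])
                start = src + int(rng.integers(0, 80))
                length = int(rng.integers(21, 24))
                n_hits = int(rng.integers(1, 3))
                reads.append(_read(start, length, n_hits, rid=f"r{seed}_{i}"))
                alns.append((start, start + length, 1.0 / n_hits))
            denom = sum(w for _, _, w in alns)
            # rpm_min chosen so that with ~25 units of mass some regions
            # fall below threshold and step 3 is actually exercised
            rpm_min = 1.5e5
            got = call_clusters_replicate(reads, rpm_min=rpm_min)
            got_t = sorted((c.start, c.end, round(c.weight, 9)) for c in got)
            assert got_t == oracle_clusters(alns, denom, rpm_min=rpm_min)

    def test_order_independence_and_mass_conservation(self):
        rng = np.random.default_rng(1)
        reads = [_read(int(rng.integers(0, 500)), rid=f"r{i}")
                 for i in range(40)]
        a = call_clusters_replicate(reads, total_weight=1e4)
        b = call_clusters_replicate(reads[::-1], total_weight=1e4)
        assert [(c.start, c.end, c.weight) for c in a] == \
               [(c.start, c.end, c.weight) for c in b]
        pre = call_clusters_replicate(reads, join_dist=-1, total_weight=1e4)
        assert sum(c.weight for c in a) == pytest.approx(
            sum(c.weight for c in pre))

    def test_monotonicity(self):
        rng = np.random.default_rng(2)
        reads = [_read(int(rng.integers(0, 3000)), rid=f"r{i}")
                 for i in range(60)]
        strict = call_clusters_replicate(reads, rpm_min=3.0, total_weight=3e5)
        loose = call_clusters_replicate(reads, rpm_min=1.0, total_weight=3e5)
        # lowering rpm_min never removes a cluster
        for c in strict:
            assert any(l.start <= c.start and l.end >= c.end for l in loose)
        near = call_clusters_replicate(reads, join_dist=200, total_weight=3e5)
        assert len(near) <= len(call_clusters_replicate(
            reads, join_dist=50, total_weight=3e5))


class TestConsolidate:
    def test_cluster_missing_from_one_replicate_dropped(self):
        r1 = [Cluster("c", 100, 160, 5.0, 10.0)]
        r2 = [Cluster("c", 120, 180, 5.0, 10.0)]
        r3 = []
        assert consolidate_genotype([r1, r2, r3]) == []

    def test_identical_replicates_idempotent(self):
        r = [Cluster("c", 100, 160, 5.0, 10.0), Cluster("c", 400, 440, 4.0, 8.0)]
        out = consolidate_genotype([r, r])
        assert [(c.start, c.end) for c in out] == [(100, 160), (400, 440)]

    def test_union_of_staggered_intervals(self):
        reps = [[Cluster("c", 100, 160, 1.0)],
                [Cluster("c", 120, 180, 1.0)],
                [Cluster("c", 110, 170, 1.0)]]
        out = consolidate_genotype(reps)
        assert [(c.start, c.end) for c in out] == [(100, 180)]


class TestAnnotate:
    LAYERS = {
        "miRNA": [GenomicInterval("c", 100, 160)],
        "TE": [GenomicInterval("c", 140, 260)],
        "mRNA": [GenomicInterval("c", 300, 500)],
        "miscRNA": [GenomicInterval("c", 450, 600)],
    }

    def test_hierarchy(self):
        c = Cluster("c", 150, 170, 1.0)   # overlaps miRNA and TE
        (out,) = annotate_clusters([c], self.LAYERS)
        assert out.category == "miRNA"

    def test_no_overlap_is_other(self):
        (out,) = annotate_clusters([Cluster("c", 1000, 1050, 1.0)], self.LAYERS)
        assert out.category == "other"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        hierarchy = ("miRNA", "TE", "mRNA", "miscRNA")
        clusters = [Cluster("c", int(s), int(s) + int(rng.integers(10, 100)), 1.0)
                    for s in rng.integers(0, 700, size=50)]
        out = annotate_clusters(clusters, self.LAYERS)
        for c, got in zip(clusters, out):
            expected = "other"
            for cat in hierarchy:
                if any(min(iv.end, c.end) - max(iv.start, c.start) >= 1
                       for iv in self.LAYERS[cat]):
                    expected = cat
                    break
            assert got.category == expected
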