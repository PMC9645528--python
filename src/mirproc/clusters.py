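"""Genome-wide small RNA cluster calling.

Four-step, per-replicate algorithm for identifying siRNA-producing loci
from 21–23 nt reads:

1. each alignment is weighted ``1/n`` where ``n`` is the read's number of
   reported loci;
2. overlapping alignments are collapsed into maximal regions, weights
   summed;
3. regions below 3 reads per million (RPM) are discarded;
4. surviving regions within 50 bp of each other are joined (transitively,
   to a fixed point), weights summed.

A genotype's final set keeps only clusters present in every replicate
(intersection), merged as the union of the overlapping replicate clusters.
Clusters are then annotated by a fixed hierarchy: miRNA > transposable
elements > mRNA > misc. RNA > other. "Within 50 bp" is read inclusively as
end-exclusive gap <= 50 (distance 0 = adjacency); clustering is
strand-blind by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .intervals import GenomicInterval
from .quantify import AlignedRead

RPM_MIN = 3.0
JOIN_DIST = 50
CLUSTER_LENGTH_RANGE = (21, 23)

HIERARCHY = ("miRNA", "TE", "mRNA", "miscRNA")


@dataclass
class Cluster:
    chrom: str
    start: int
    end: int
    weight: float
    rpm: float = 0.0
    category: Optional[str] = None
    strand: str = "."

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               "+" if self.strand == "." else self.strand)


def _collapse(regions: List[Cluster], max_gap: int) -> List[Cluster]:
    """Merge regions whose gap is <= max_gap (overlap for max_gap < 0 is
    still a merge since gap is negative), summing weights."""
    out: List[Cluster] = []
    for c in sorted(regions, key=lambda c: (c.chrom, c.start, c.end)):
        if out and out[-1].chrom == c.chrom and c.start - out[-1].end <= max_gap:
            last = out[-1]
            last.end = max(last.end, c.end)
            last.weight += c.weight
            last.rpm += c.rpm
        else:
            out.append(replace(c))
    return out


def call_clusters_replicate(
    reads: Iterable[AlignedRead],
    rpm_min: float = RPM_MIN,
    join_dist: int = JOIN_DIST,
    length_range: Tuple[int, int] = CLUSTER_LENGTH_RANGE,
    total_weight: Optional[float] = None,
    stranded: bool = False,
) -> List[Cluster]:
    """Run the four-step algorithm on one replicate's alignments.

    ``total_weight`` overrides the RPM denominator; by default it is the
    total 1/n-weighted mass of length-selected alignments in this replicate.
    """
    lmin, lmax = length_range
    regions: List[Cluster] = []
    mass = 0.0
    for read in reads:
        if not (lmin <= read.length <= lmax):
            continue
        w = 1.0 / read.n_hits
        for aln in read.alignments:
            regions.append(Cluster(aln.chrom, aln.start, aln.end, w,
                                   strand=aln.strand if stranded else "."))
            mass += w
    denom = total_weight if total_weight is not None else mass
    if denom <= 0:
        return []
    if stranded:
        by_strand: Dict[str, List[Cluster]] = {}
        for r in regions:
            by_strand.setdefault(r.strand, []).append(r)
        groups = list(by_strand.values())
    else:
        groups = [regions]
    final: List[Cluster] = []
    for grp in groups:
        collapsed = _collapse(grp, max_gap=-1)          # step 2: overlap only
        for c in collapsed:
            c.rpm = 1e6 * c.weight / denom
        survivors = [c for c in collapsed if c.rpm >= rpm_min]  # step 3
        final.extend(_collapse(survivors, max_gap=join_dist))   # step 4
    return sorted(final, key=lambda c: (c.chrom, c.start, c.end))


def consolidate_genotype(replicate_sets: Sequence[Sequence[Cluster]]) -> List[Cluster]:
    """Intersect replicate cluster sets into the genotype set.

    A genotype cluster is a maximal group of mutually overlapping replicate
    clusters (transitive overlap) that includes at least one cluster from
    every replicate; its coordinates are the union of the group. Per-cluster
    weight/rpm are the means over replicates of the contributing clusters.
    """
    n_rep = len(replicate_sets)
    if n_rep == 0:
        raise ValueError("need at least one replicate")
    tagged = [
        (c, r) for r, clusters in enumerate(replicate_sets) for c in clusters
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: List[Cluster] = []
    group: List[Tuple[Cluster, int]] = []

    def _flush():
        if not group:
            return
        reps = {r for _, r in group}
        if len(reps) == n_rep:
            start = min(c.start for c, _ in group)
            end = max(c.end for c, _ in group)
            w = sum(c.weight for c, _ in group) / n_rep
            rpm = sum(c.rpm for c, _ in group) / n_rep
            out.append(Cluster(group[0][0].chrom, start, end, w, rpm))

    cur_chrom, cur_end = None, -1
    for c, r in tagged:
        if c.chrom != cur_chrom or c.start >= cur_end:
            _flush()
            group = []
            cur_chrom, cur_end = c.chrom, c.end
        group.append((c, r))
        cur_end = max(cur_end, c.end)
    _flush()
    return out


def annotate_clusters(
    clusters: Iterable[Cluster],
    layers: Dict[str, Sequence[GenomicInterval]],
    hierarchy: Sequence[str] = HIERARCHY,
) -> List[Cluster]:
    """Assign each cluster the highest-priority category it overlaps
    (any overlap >= 1 nt, strand-blind); no overlap -> ``other``."""
    annotated = []
    for c in clusters:
        category = "other"
        for cat in hierarchy:
            ivs = layers.get(cat, ())
            if any(iv.chrom == c.chrom and
                   min(iv.end, c.end) - max(iv.start, c.start) >= 1
                   for iv in ivs):
                category = cat
                break
        annotated.append(replace(c, category=category))
    return annotated


def write_bed(clusters: Iterable[Cluster], path: Union[str, Path]) -> None:
    """BED6 with weight in column 5 and RPM / category appended."""
    lines = []
    for i, c in enumerate(sorted(clusters, key=lambda c: (c.chrom, c.start))):
        lines.append("\t".join([
            c.chrom, str(c.start), str(c.end), f"cluster_{i + 1}",
            f"{c.weight:.4f}", c.strand, f"{c.rpm:.4f}", c.category or ".",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
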