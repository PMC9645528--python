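"""Feature counting and normalization statistics.

Counting follows small RNA-seq practice for miRNA quantification: only
reads of 19–25 nt are counted, an alignment is assigned to a mature miRNA
feature only with sense-strand overlap of at least 15 nt, and multimapping
reads are down-weighted so each read contributes total mass 1 — a read with
``n`` reported alignments, an alignment hitting ``m`` qualifying features,
adds ``1/(n*m)`` to each of those features.

Normalization re-implements the DESeq2 quantities the downstream
classification consumes: median-of-ratios size factors, baseMean (mean of
size-factor-normalized counts over all samples) and a plain log2 fold
change between group means with a pseudocount. Negative-binomial testing
(p-values, shrunken fold changes) is deliberately not reproduced here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

LENGTH_RANGE = (19, 25)
MIN_OVERLAP = 15


@dataclass
class AlignedRead:
    """One sequenced read with all its reported alignments."""

    read_id: str
    sample: str
    length: int
    alignments: List[GenomicInterval]
    n_hits: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_hits is None:
            self.n_hits = len(self.alignments)
        if self.n_hits < 1 or not self.alignments:
            raise ValueError(f"{self.read_id}: needs >= 1 alignment")


@dataclass
class CountTable:
    """Feature x sample fractional counts plus derived statistics."""

    counts: pd.DataFrame                       # features x samples
    length_totals: pd.DataFrame                # read length x samples (weighted)
    size_factors: Optional[pd.Series] = None
    base_mean: Optional[pd.Series] = None
    log2fc: Optional[pd.Series] = None

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def denominator(self, kind: str = "all_counted") -> pd.Series:
        """Per-sample read totals for per-million scaling."""
        if kind == "all_counted":
            return self.length_totals.sum(axis=0)
        if kind == "length_21_23":
            sel = self.length_totals.loc[
                [l for l in self.length_totals.index if 21 <= l <= 23]]
            return sel.sum(axis=0)
        raise ValueError(f"unknown denominator kind {kind!r}")


def reads_from_sam(path, sample: str) -> List[AlignedRead]:
    """Group a SAM/BAM file's alignments into AlignedRead objects.

    The hit count comes from the NH tag when present, otherwise from the
    number of records sharing the read name (1 if unique).
    """
    grouped: Dict[str, List[GenomicInterval]] = {}
    nh: Dict[str, int] = {}
    lengths: Dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            iv = GenomicInterval(
                rec.reference_name, rec.reference_start, rec.reference_end,
                "-" if rec.is_reverse else "+",
            )
            grouped.setdefault(rec.query_name, []).append(iv)
            lengths[rec.query_name] = rec.query_length or iv.length
            if rec.has_tag("NH"):
                nh[rec.query_name] = rec.get_tag("NH")
    return [
        AlignedRead(rid, sample, lengths[rid], ivs, nh.get(rid, len(ivs)))
        for rid, ivs in grouped.items()
    ]


def _build_trees(features: Sequence[Tuple[str, GenomicInterval]]):
    trees: Dict[str, IntervalTree] = {}
    for name, iv in features:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (name, iv))
    return trees


def count_features(
    reads_by_sample: Dict[str, Iterable[AlignedRead]],
    features: Sequence[Tuple[str, GenomicInterval]],
    min_overlap: int = MIN_OVERLAP,
    length_range: Tuple[int, int] = LENGTH_RANGE,
    stranded: bool = True,
    fraction: bool = True,
) -> CountTable:
    """Fractionally count reads over features for each sample."""
    if not features:
        warnings.warn("empty annotation: returning an empty count table")
    trees = _build_trees(features)
    feat_names = [name for name, _ in features]
    samples = list(reads_by_sample)
    counts = pd.DataFrame(0.0, index=feat_names, columns=samples)
    lmin, lmax = length_range
    length_totals = pd.DataFrame(0.0, index=range(lmin, lmax + 1), columns=samples)

    for sample, reads in reads_by_sample.items():
        for read in reads:
            if not (lmin <= read.length <= lmax):
                continue
            length_totals.loc[read.length, sample] += 1.0
            per_aln = 1.0 / read.n_hits
            for aln in read.alignments:
                tree = trees.get(aln.chrom)
                if tree is None:
                    continue
                hits = []
                for node in tree.overlap(aln.start, aln.end):
                    name, fiv = node.data
                    if stranded and fiv.strand != aln.strand:
                        continue
                    if aln.overlap_len(fiv) >= min_overlap:
                        hits.append(name)
                if not hits:
                    continue
                w = per_aln / len(hits) if fraction else per_aln
                for name in hits:
                    counts.loc[name, sample] += w
    return CountTable(counts=counts, length_totals=length_totals)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over features detected in every sample.

    Falls back to total-count scaling (factors proportional to column sums,
    geometric mean 1) with a warning when no feature is all-nonzero.
    """
    all_nonzero = counts[(counts > 0).all(axis=1)]
    if all_nonzero.empty:
        warnings.warn("no feature detected in all samples; "
                      "falling back to total-count scaling")
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot normalize: a sample has zero total counts")
        return totals / np.exp(np.log(totals).mean())
    log_geo = np.log(all_nonzero).mean(axis=1)
    ratios = np.log(all_nonzero).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def base_mean_and_lfc(
    table: CountTable,
    contrast: Tuple[Sequence[str], Sequence[str]],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """baseMean over all samples and log2((meanB+pc)/(meanA+pc)) per feature."""
    group_a, group_b = contrast
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both contrast groups must be non-empty")
    sf = table.size_factors if table.size_factors is not None else size_factors(table.counts)
    norm = table.counts.div(sf, axis=1)
    base_mean = norm.mean(axis=1)
    mean_a = norm[list(group_a)].mean(axis=1)
    mean_b = norm[list(group_b)].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    table.size_factors = sf
    table.base_mean = base_mean
    table.log2fc = lfc
    return pd.DataFrame({"base_mean": base_mean, "log2fc": lfc})


def cpm_normalize(table: CountTable, denominator: str = "all_counted") -> pd.DataFrame:
    """Scale each sample to counts per million of the chosen read class
    (``all_counted`` 19–25 nt, or ``length_21_23``)."""
    denom = table.denominator(denominator)
    if (denom <= 0).any():
        raise ValueError(f"zero {denominator} denominator for samples "
                         f"{list(denom.index[denom <= 0])}")
    return table.counts.div(denom, axis=1) * 1e6
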