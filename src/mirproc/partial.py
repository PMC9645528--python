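"""Partial precursor processing analysis.

Dicer normally makes two coupled cuts on a pre-miRNA; asymmetric (partial)
cleavage cuts only one strand position — e.g. only at the 5' end of the 3p
miRNA, leaving a 5p-arm + loop fragment. This module categorizes every
read sense-overlapping a precursor by matching its ends, with a +/-2 nt
tolerance per boundary, against templates built from the precursor
boundaries and the two cleavage points (precursor-local, 1-based):

========================  ===========================================
category                  template (start, end)
========================  ===========================================
precursor                 (1, L)
partial_5prime_fragment   (1, cp_3p5 - 1)   5p arm + loop
partial_3prime_fragment   (cp_5p3 + 1, L)   loop + 3p arm
miRNA_5p                  (1, cp_5p3)
miRNA_3p                  (cp_3p5, L)
loop_fragment             (cp_5p3 + 1, cp_3p5 - 1)
other                     anything else
========================  ===========================================

Templates are tested most-specific-span first (the order above), so every
read lands in exactly one category. The category set is a reconstruction
of the minimal complete partition implied by "boundaries plus the two
cleavage points"; see docs/methods.md.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .hairpin import HairpinLocus
from .quantify import AlignedRead

TOLERANCE = 2

CATEGORIES = (
    "precursor",
    "partial_5prime_fragment",
    "partial_3prime_fragment",
    "miRNA_5p",
    "miRNA_3p",
    "loop_fragment",
    "other",
)


def category_templates(h: HairpinLocus) -> Dict[str, Tuple[int, int]]:
    """Precursor-local (start, end) template per category, precedence order."""
    if h.cp_5p3 is None or h.cp_3p5 is None:
        raise ValueError(f"{h.id}: both cleavage points required")
    L = len(h.sequence)
    return {
        "precursor": (1, L),
        "partial_5prime_fragment": (1, h.cp_3p5 - 1),
        "partial_3prime_fragment": (h.cp_5p3 + 1, L),
        "miRNA_5p": (1, h.cp_5p3),
        "miRNA_3p": (h.cp_3p5, L),
        "loop_fragment": (h.cp_5p3 + 1, h.cp_3p5 - 1),
    }


def categorize_read(lo: int, hi: int, templates: Dict[str, Tuple[int, int]],
                    tol: int = TOLERANCE) -> str:
    """Category of a read spanning local positions ``lo..hi`` (1-based)."""
    for cat, (ts, te) in templates.items():
        if abs(lo - ts) <= tol and abs(hi - te) <= tol:
            return cat
    return "other"


def categorize_reads(
    reads: Iterable[AlignedRead],
    h: HairpinLocus,
    tol: int = TOLERANCE,
) -> pd.DataFrame:
    """Count and percentage per category of all reads sense-overlapping
    ``h``. Percentages are over the total of overlapping reads and sum to
    100 whenever any read overlaps."""
    templates = category_templates(h)
    counts = {cat: 0 for cat in CATEGORIES}
    hv = h.interval
    for read in reads:
        for aln in read.alignments:
            if aln.chrom != hv.chrom or aln.strand != hv.strand:
                continue
            if min(aln.end, hv.end) <= max(aln.start, hv.start):
                continue
            # local ends; reads may poke past the precursor, clamp via raw math
            if hv.strand == "+":
                lo, hi = aln.start - hv.start + 1, aln.end - hv.start
            else:
                lo, hi = hv.end - aln.end + 1, hv.end - aln.start
            counts[categorize_read(lo, hi, templates, tol)] += 1
            break  # one (sense) assignment per read at this locus
    total = sum(counts.values())
    out = pd.DataFrame({
        "count": pd.Series(counts),
    })
    out["percent"] = 100.0 * out["count"] / total if total else np.nan
    out.attrs["total_reads"] = total
    return out


def categorize_by_locus(
    reads: Iterable[AlignedRead],
    loci: Sequence[HairpinLocus],
    tol: int = TOLERANCE,
) -> Dict[str, pd.DataFrame]:
    """Single-pass categorization of a read stream over many loci.

    Equivalent to calling :func:`categorize_reads` per locus, but reads are
    routed to loci through an interval index instead of rescanning the
    stream. Loci without both cleavage points are skipped.
    """
    usable = [h for h in loci if h.cp_5p3 is not None and h.cp_3p5 is not None]
    templates = {h.id: category_templates(h) for h in usable}
    counts = {h.id: {cat: 0 for cat in CATEGORIES} for h in usable}
    by_id = {h.id: h for h in usable}
    trees: Dict[str, IntervalTree] = {}
    for h in usable:
        trees.setdefault(h.interval.chrom, IntervalTree()).addi(
            h.interval.start, h.interval.end, h.id)
    for read in reads:
        for aln in read.alignments:
            tree = trees.get(aln.chrom)
            if tree is None:
                continue
            for node in tree.overlap(aln.start, aln.end):
                h = by_id[node.data]
                hv = h.interval
                if aln.strand != hv.strand:
                    continue
                if hv.strand == "+":
                    lo, hi = aln.start - hv.start + 1, aln.end - hv.start
                else:
                    lo, hi = hv.end - aln.end + 1, hv.end - aln.start
                counts[h.id][categorize_read(lo, hi, templates[h.id], tol)] += 1
    out = {}
    for hid, c in counts.items():
        tab = pd.DataFrame({"count": pd.Series(c)})
        total = tab["count"].sum()
        tab["percent"] = 100.0 * tab["count"] / total if total else np.nan
        tab.attrs["total_reads"] = int(total)
        out[hid] = tab
    return out


def partial_fraction_table(
    tables_by_condition: Dict[str, Dict[str, pd.DataFrame]],
    category: str = "partial_5prime_fragment",
    contrast: Optional[Tuple[str, str]] = None,
) -> pd.DataFrame:
    """Per-locus percentage of a category per condition, with the
    mutant - wild-type difference when ``contrast=(wt, mutant)`` is given.

    Loci with zero overlapping reads in a condition get NaN and are flagged.
    """
    conditions = list(tables_by_condition)
    loci = sorted({l for tabs in tables_by_condition.values() for l in tabs})
    data = {}
    flagged = {}
    for cond in conditions:
        col = []
        flag = []
        for locus in loci:
            tab = tables_by_condition[cond].get(locus)
            if tab is None or tab.attrs.get("total_reads", 0) == 0:
                col.append(np.nan)
                flag.append(True)
            else:
                col.append(tab.loc[category, "percent"])
                flag.append(False)
        data[cond] = col
        flagged[cond] = flag
    out = pd.DataFrame(data, index=loci)
    for cond in conditions:
        out[f"no_reads_{cond}"] = flagged[cond]
    if contrast is not None:
        wt, mut = contrast
        out["difference"] = out[mut] - out[wt]
        out = out.sort_values("difference", ascending=False, kind="mergesort")
    return out
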