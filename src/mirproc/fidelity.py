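"""Cleavage-point (5'-end / 3'-end) fidelity analysis.

For each sufficiently expressed miRNA the two Dicer cleavage points (CPs)
on its precursor are interrogated with read ends: 5' starts of reads around
the 5'-CP of the 3p arm, and 3' ends of reads around the 3'-CP of the 5p
arm, in a +/-15 nt window. Offsets are oriented 5'->3' along the mature
miRNA regardless of genomic strand, so a positive offset always means a
shortened mature (the end shifted into the miRNA).

The canonical CP is then re-defined from wild-type data only:

1. the position with maximal counts (median among replicates) becomes the
   new CP;
2. if it lies more than 7 nt from the canonical one, keep the canonical;
3. ties at the maximum keep the canonical;
4. no reads keep the canonical.

Counts at the new CP +/-5 are converted to window-local densities (unit
sum over the 11 positions) per group, and the wild-type density row is
subtracted from the mutant's; each difference row therefore sums to zero.
The top-k selection ranks rows by |difference at the CP| in one dataset and
orders the picked rows by the signed difference at the CP in another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .hairpin import HairpinLocus
from .quantify import AlignedRead

WINDOW = 15            # +/- nt collected around the canonical CP
MAX_CP_SHIFT = 7       # rule 2 bound on CP redefinition
FLANK = 5              # +/- nt of the density rows
BASE_MEAN_GATE = 100.0

END_KINDS = ("start_at_3p5CP", "end_at_5p3CP")


@dataclass
class FidelityProfile:
    """Read-end count window around one cleavage point of one miRNA."""

    mirna_id: str
    end_kind: str                       # which CP / which read end
    windows: np.ndarray                 # (n_replicates, 2*WINDOW+1) counts
    redefined_cp_offset: int = 0
    density: Optional[np.ndarray] = None
    diff: Optional[np.ndarray] = None


def collect_end_profiles(
    reads_by_replicate: Sequence[Iterable[AlignedRead]],
    loci: Sequence[HairpinLocus],
    window: int = WINDOW,
    length_range: Tuple[int, int] = (19, 25),
) -> Dict[Tuple[str, str], np.ndarray]:
    """Tally read end positions around both CPs of each locus.

    Returns ``{(mirna_end_id, end_kind): (n_replicates, 2*window+1)}`` count
    arrays, where the center column is the canonical CP. Loci lacking a CP
    are skipped. The caller applies any expression gate (e.g. baseMean >=
    100) by pre-filtering ``loci``.
    """
    lmin, lmax = length_range
    width = 2 * window + 1
    n_rep = len(reads_by_replicate)
    profiles: Dict[Tuple[str, str], np.ndarray] = {}
    locus_list = [h for h in loci if h.cp_5p3 is not None and h.cp_3p5 is not None]
    trees: Dict[str, IntervalTree] = {}
    for h in locus_list:
        trees.setdefault(h.interval.chrom, IntervalTree()).addi(
            h.interval.start, h.interval.end, h)
        for arm, name in (("3p", h.name3p), ("5p", h.name5p)):
            key_id = (name or f"{h.id}-{arm}")
            kind = "start_at_3p5CP" if arm == "3p" else "end_at_5p3CP"
            profiles[(key_id, kind)] = np.zeros((n_rep, width))

    for r, reads in enumerate(reads_by_replicate):
        for read in reads:
            if not (lmin <= read.length <= lmax):
                continue
            for aln in read.alignments:
                tree = trees.get(aln.chrom)
                if tree is None:
                    continue
                for node in tree.overlap(aln.start, aln.end):
                    h = node.data
                    hv = h.interval
                    if aln.strand != hv.strand:
                        continue
                    # local, 1-based ends of the read on the precursor
                    if hv.strand == "+":
                        lo = aln.start - hv.start + 1
                        hi = aln.end - hv.start
                    else:
                        lo = hv.end - aln.end + 1
                        hi = hv.end - aln.start
                    off3 = lo - h.cp_3p5          # 5' start vs 5'-CP of 3p
                    off5 = h.cp_5p3 - hi          # 3' end vs 3'-CP of 5p
                    if abs(off3) <= window:
                        key = ((h.name3p or f"{h.id}-3p"), "start_at_3p5CP")
                        profiles[key][r, window + off3] += 1
                    if abs(off5) <= window:
                        key = ((h.name5p or f"{h.id}-5p"), "end_at_5p3CP")
                        profiles[key][r, window + off5] += 1
    return profiles


def redefine_cp(wt_windows: np.ndarray, window: int = WINDOW,
                max_shift: int = MAX_CP_SHIFT) -> int:
    """New CP offset from wild-type replicate windows (0 keeps canonical).

    Median counts across replicates, argmax position; canonical is kept on
    empty windows, ties at the maximum, or shifts beyond ``max_shift``.
    """
    med = np.median(np.asarray(wt_windows, dtype=float), axis=0)
    if not med.any():
        return 0
    mx = med.max()
    at_max = np.flatnonzero(med == mx)
    if len(at_max) != 1:
        return 0
    offset = int(at_max[0]) - window
    if abs(offset) > max_shift:
        return 0
    return offset


def _density(windows: np.ndarray, center: int, flank: int) -> Tuple[np.ndarray, bool]:
    counts = np.asarray(windows, dtype=float).sum(axis=0)
    row = counts[center - flank:center + flank + 1]
    total = row.sum()
    if total <= 0:
        return np.zeros(2 * flank + 1), True
    return row / total, False


def fidelity_matrix(
    mutant_profiles: Dict[Tuple[str, str], np.ndarray],
    wt_profiles: Dict[Tuple[str, str], np.ndarray],
    window: int = WINDOW,
    flank: int = FLANK,
    max_shift: int = MAX_CP_SHIFT,
) -> pd.DataFrame:
    """Mutant - wild-type density rows at the redefined CP +/- flank.

    CP redefinition uses the wild-type windows only. Returns a frame
    indexed by (miRNA id, end kind) with offset columns -flank..+flank,
    plus ``new_cp_offset`` and a ``flagged`` column marking rows where a
    group had zero reads in the extraction window.
    """
    rows = {}
    offsets = list(range(-flank, flank + 1))
    for key in sorted(wt_profiles):
        if key not in mutant_profiles:
            continue
        new_off = redefine_cp(wt_profiles[key], window=window, max_shift=max_shift)
        center = window + new_off
        wt_d, wt_flag = _density(wt_profiles[key], center, flank)
        mu_d, mu_flag = _density(mutant_profiles[key], center, flank)
        rows[key] = list(mu_d - wt_d) + [new_off, wt_flag or mu_flag]
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["mirna", "end_kind"])
    return pd.DataFrame(
        list(rows.values()), index=idx,
        columns=offsets + ["new_cp_offset", "flagged"],
    )


def select_and_order(
    diff: pd.DataFrame,
    order_diff: Optional[pd.DataFrame] = None,
    k: int = 50,
) -> pd.DataFrame:
    """Pick the k rows with largest |difference at the CP| and order them by
    the signed CP difference in ``order_diff`` (defaults to ``diff``).

    ``diff``/``order_diff`` are outputs of :func:`fidelity_matrix`; rows
    missing from ``order_diff`` sort last.
    """
    if order_diff is None:
        order_diff = diff
    center = diff[0].abs()
    if len(diff) < k:
        warnings.warn(f"only {len(diff)} rows available for top-{k} selection")
    picked = center.sort_values(ascending=False, kind="mergesort").index[:k]
    order_key = order_diff[0].reindex(picked)
    ordered = order_key.sort_values(ascending=False, kind="mergesort",
                                    na_position="last").index
    return diff.loc[ordered]


def recovered_shift(diff_row: Sequence[float], flank: int = FLANK) -> int:
    """Offset of the maximal positive mutant-WT difference.

    Ties resolve to the smallest |offset|; an all-zero row has no defined
    shift and raises ``ValueError``.
    """
    if isinstance(diff_row, pd.Series):
        offsets = [o for o in diff_row.index if isinstance(o, (int, np.integer))]
        row = diff_row[offsets].to_numpy(dtype=float)
        flank = max(abs(int(o)) for o in offsets)
    else:
        row = np.asarray(diff_row, dtype=float)
        flank = (len(row) - 1) // 2
    if not row.any():
        raise ValueError("all-zero difference row: shift undefined")
    mx = row.max()
    if mx <= 0:
        raise ValueError("no positive difference: shift undefined")
    candidates = [i - flank for i in np.flatnonzero(row == mx)]
    return min(candidates, key=lambda o: (abs(o), o))
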