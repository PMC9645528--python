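"""Pre-miRNA hairpin geometry.

A pre-miRNA is a stem-loop RNA that Dicer cleaves once, releasing a small
RNA duplex (the future 5p and 3p mature strands) and a terminal loop. This
module models that geometry directly on the sequence:

* :func:`cleave_hairpin` — split a precursor at the two scissile positions
  into 5p strand, loop and 3p strand;
* :func:`fold_stem` — contiguous base-pairing geometry (stem length, loop
  length, end overhangs) of a hairpin, pairing from the termini inward;
* :func:`mirtron_extension_score` — stem/loop extension of a locus relative
  to a reference geometry, used to flag mirtron-like precursors with
  extended stems and enlarged loops.

Precursor-local positions are 1-based throughout ("between bases G22 and
G23" style), while genomic coordinates elsewhere in the package are 0-based
half-open. ``fold_stem`` is a deliberate contiguous-pairing approximation,
not a thermodynamic (MFE) folder: it reproduces perfect-duplex substrates
exactly and is only a descriptive score on imperfect natural hairpins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from .intervals import GenomicInterval

RNA_ALPHABET = set("ACGUN")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def as_rna(seq: str) -> str:
    """Uppercase and map T->U; reject characters outside {A,C,G,U,N}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return as_rna(seq).translate(_COMPLEMENT)[::-1]


def _pairs(a: str, b: str, allow_wobble: bool) -> bool:
    if (a, b) in _WC:
        return True
    return allow_wobble and (a, b) in _WOBBLE


@dataclass(frozen=True)
class CleavageProduct:
    """The three pieces released by cleaving a precursor at two positions."""

    strand5p: str
    loop: str
    strand3p: str

    @property
    def duplex_len5p(self) -> int:
        return len(self.strand5p)

    @property
    def duplex_len3p(self) -> int:
        return len(self.strand3p)

    def reassemble(self) -> str:
        return self.strand5p + self.loop + self.strand3p


@dataclass(frozen=True)
class StemGeometry:
    """Contiguous-pairing geometry of a hairpin.

    Satisfies ``2*stem_len + loop_len + overhang5 + overhang3 == input length``.
    """

    stem_len: int
    loop_len: int
    overhang5: int = 0
    overhang3: int = 0


@dataclass
class HairpinLocus:
    """A pre-miRNA locus.

    Mature arm intervals and cleavage points are precursor-local, 1-based
    inclusive. ``cp_5p3`` is the last nucleotide of the 5p arm (the 3'-CP of
    miRNA-5p); ``cp_3p5`` is the first nucleotide of the 3p arm (the 5'-CP
    of miRNA-3p).
    """

    id: str
    interval: GenomicInterval
    sequence: str
    mature5p: Optional[Tuple[int, int]] = None
    mature3p: Optional[Tuple[int, int]] = None
    cp_5p3: Optional[int] = None
    cp_3p5: Optional[int] = None
    is_mirtron: bool = False
    name5p: Optional[str] = None
    name3p: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = as_rna(self.sequence)
        L = len(self.sequence)
        for arm in (self.mature5p, self.mature3p):
            if arm is not None:
                lo, hi = arm
                if not (1 <= lo <= hi <= L):
                    raise ValueError(
                        f"{self.id}: mature interval {arm} outside precursor 1..{L}"
                    )
        if self.mature5p and self.mature3p:
            if self.mature5p[1] >= self.mature3p[0]:
                raise ValueError(f"{self.id}: mature arms overlap")
            if self.cp_5p3 is None:
                self.cp_5p3 = self.mature5p[1]
            if self.cp_3p5 is None:
                self.cp_3p5 = self.mature3p[0]
        if self.cp_5p3 is not None and self.cp_3p5 is not None:
            if not (1 <= self.cp_5p3 < self.cp_3p5 <= L):
                raise ValueError(
                    f"{self.id}: cleavage points ({self.cp_5p3}, {self.cp_3p5}) "
                    f"violate 1 <= cp_5p3 < cp_3p5 <= {L}"
                )

    # -- coordinate conversion ------------------------------------------------

    def genomic_to_local(self, start: int, end: int) -> Tuple[int, int]:
        """Map a genomic 0-based half-open interval to 1-based inclusive
        precursor-local positions, strand-aware (local position 1 is the
        precursor 5' end)."""
        h = self.interval
        if not (h.start <= start < end <= h.end):
            raise ValueError(
                f"[{start},{end}) not inside hairpin {self.id} "
                f"[{h.start},{h.end})"
            )
        if h.strand == "+":
            return start - h.start + 1, end - h.start
        return h.end - end + 1, h.end - start

    def local_to_genomic(self, lo: int, hi: int) -> Tuple[int, int]:
        """Inverse of :meth:`genomic_to_local`; returns 0-based half-open."""
        L = len(self.sequence)
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"local positions {lo}..{hi} outside 1..{L}")
        h = self.interval
        if h.strand == "+":
            return h.start + lo - 1, h.start + hi
        return h.end - hi, h.end - lo + 1


def cleave_hairpin(precursor, cut5: int, cut3: int) -> CleavageProduct:
    """Cleave a precursor after position ``cut5`` and before position ``cut3``.

    ``cut5`` is the last nucleotide of the 5p strand, ``cut3`` the first of
    the 3p strand (both 1-based).  The loop is everything in between and
    must be non-empty (``cut3 - cut5 >= 2``).
    """
    seq = precursor.sequence if isinstance(precursor, HairpinLocus) else as_rna(precursor)
    L = len(seq)
    if not (1 <= cut5 < cut3 <= L):
        raise ValueError(f"cuts ({cut5}, {cut3}) out of range for length {L}")
    if cut3 - cut5 < 2:
        raise ValueError("loop between the cuts would be empty")
    return CleavageProduct(
        strand5p=seq[:cut5],
        loop=seq[cut5:cut3 - 1],
        strand3p=seq[cut3 - 1:],
    )


def fold_stem(seq: str, allow_wobble: bool = False, max_end_overhang: int = 4,
              min_loop: int = 3) -> StemGeometry:
    """Geometry of the maximal contiguous terminal stem of a hairpin.

    For every pair of 5'/3' end overhang lengths up to ``max_end_overhang``,
    pair the (offset-trimmed) termini inward while bases are complementary
    (Watson-Crick; G.U admitted only with ``allow_wobble``) and at least
    ``min_loop`` unpaired nucleotides would remain between the innermost
    pair.  Returns the geometry maximizing stem length; ties prefer the
    smallest total overhang, then the smallest 5' overhang.
    """
    s = as_rna(seq)
    L = len(s)
    if L < 8:
        raise ValueError("sequence too short to fold (need >= 8 nt)")
    best = StemGeometry(stem_len=0, loop_len=L, overhang5=0, overhang3=0)
    best_key = (0, 0, 0)
    for o5 in range(max_end_overhang + 1):
        for o3 in range(max_end_overhang + 1):
            i, j = o5, L - 1 - o3
            stem = 0
            while j - i - 1 >= min_loop and _pairs(s[i], s[j], allow_wobble):
                stem += 1
                i += 1
                j -= 1
            key = (stem, -(o5 + o3), -o5)
            if stem > 0 and key > best_key:
                best_key = key
                best = StemGeometry(
                    stem_len=stem,
                    loop_len=L - o5 - o3 - 2 * stem,
                    overhang5=o5,
                    overhang3=o3,
                )
    return best


def mirtron_extension_score(h: HairpinLocus, stem_ref: int, loop_ref: int,
                            allow_wobble: bool = False,
                            max_end_overhang: int = 4):
    """Stem/loop extension of a hairpin relative to a reference geometry.

    Returns ``(delta_stem, delta_loop, extended)`` where ``extended`` is
    true when either delta is positive — the signature of strongly
    upregulated mirtron-like precursors (extended stems, larger loops).
    """
    geo = fold_stem(h.sequence, allow_wobble=allow_wobble,
                    max_end_overhang=max_end_overhang)
    delta_stem = geo.stem_len - stem_ref
    delta_loop = geo.loop_len - loop_ref
    return delta_stem, delta_loop, (delta_stem > 0 or delta_loop > 0)
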