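"""Genomic coordinate primitives.

Internal convention everywhere in this package: 0-based, half-open
``[start, end)`` intervals, the natural system for overlap arithmetic.
GFF3 input/output converts to/from that format's 1-based inclusive
coordinates at the boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases, ignoring strand (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1,
                 stranded: bool = False) -> bool:
        if stranded and self.strand != other.strand:
            return False
        return self.overlap_len(other) >= min_overlap

    def gap_to(self, other: "GenomicInterval") -> int:
        """End-exclusive gap between two intervals on the same chromosome.

        0 means adjacent, negative means overlapping.
        """
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if other.start >= self.end:
            return other.start - self.end
        if self.start >= other.end:
            return self.start - other.end
        return -self.overlap_len(other)
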