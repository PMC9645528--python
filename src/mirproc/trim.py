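"""Small RNA-seq read trimming.

Implements the two-round trimming layout used for NEXTflex-style small RNA
libraries: 4 random bases on the left, then repeated 5'/3' adapter removal,
terminal-N trimming and length / N-content filtering. This is an
approximate re-implementation of the published cutadapt invocation
(mismatch-only semi-global matching, no indels); the pinned parameters —
error rate 0.075, minimum overlap 14, two rounds, minimum length 12,
maximum N fraction 0.1 — are the defaults of :class:`TrimConfig`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple, Union

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: NEXTflex 3' adapter as searched for, including the 4 random bases that
#: precede it on the read; N matches anything when wildcards are on.
ADAPTER3 = "NNNNTGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATCNNNN"

FastqRecord = Tuple[str, str, str]  # (id, sequence, quality)


@dataclass
class TrimConfig:
    left_trim: int = 4
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    error_rate: float = 0.075
    min_overlap: int = 14
    rounds: int = 2
    min_length: int = 12
    max_n_fraction: float = 0.1
    trim_terminal_n: bool = True
    match_wildcards: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def _mismatches(a: str, b: str, wildcards: bool) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        if wildcards and (x == "N" or y == "N"):
            continue
        mm += 1
    return mm


def _find_adapter3(seq: str, adapter: str, cfg: TrimConfig) -> int:
    """Leftmost read position where the 3' adapter starts, or -1.

    The adapter may run off the read's 3' end; the overlap must be at least
    ``min_overlap`` with mismatch fraction <= ``error_rate``. Scanning left
    to right makes ties resolve to the longest trimmed suffix.
    """
    n = len(seq)
    for i in range(0, n - cfg.min_overlap + 1):
        k = min(len(adapter), n - i)
        if k < cfg.min_overlap:
            break
        if _mismatches(seq[i:i + k], adapter[:k], cfg.match_wildcards) <= cfg.error_rate * k:
            return i
    return -1


def _find_adapter5(seq: str, adapter: str, cfg: TrimConfig) -> int:
    """Length of the read prefix matching the 5' adapter's 3' end, or 0."""
    kmax = min(len(adapter), len(seq))
    for k in range(kmax, cfg.min_overlap - 1, -1):
        if _mismatches(seq[:k], adapter[-k:], cfg.match_wildcards) <= cfg.error_rate * k:
            return k
    return 0


def trim_record(seq: str, qual: str, cfg: TrimConfig) -> Tuple[str, str]:
    """Apply left trim, adapter rounds and terminal-N trimming to one read."""
    seq, qual = seq[cfg.left_trim:], qual[cfg.left_trim:]
    for _ in range(cfg.rounds):
        if not seq:
            break
        k = _find_adapter5(seq, cfg.adapter5, cfg)
        if k:
            seq, qual = seq[k:], qual[k:]
        if not seq:
            break
        i = _find_adapter3(seq, cfg.adapter3, cfg)
        if i >= 0:
            seq, qual = seq[:i], qual[:i]
    if cfg.trim_terminal_n:
        stripped = seq.strip("N")
        if len(stripped) != len(seq):
            lo = seq.index(stripped) if stripped else 0
            seq, qual = stripped, qual[lo:lo + len(stripped)]
    return seq, qual


def trim_reads(records: Iterable[FastqRecord],
               cfg: TrimConfig = TrimConfig()) -> Tuple[List[FastqRecord], pd.DataFrame]:
    """Trim a FASTQ stream; returns kept records and a per-read disposition log.

    Dispositions: ``kept``, ``too_short`` (post-trim length < min_length),
    ``too_many_n`` (N fraction > max_n_fraction).
    """
    kept: List[FastqRecord] = []
    log_rows = []
    for rid, seq, qual in records:
        if len(seq) != len(qual):
            raise IOError(f"malformed FASTQ record {rid!r}: "
                          "sequence/quality length mismatch")
        tseq, tqual = trim_record(seq.upper(), qual, cfg)
        if len(tseq) < cfg.min_length:
            disposition = "too_short"
        elif tseq.count("N") > cfg.max_n_fraction * len(tseq):
            disposition = "too_many_n"
        else:
            disposition = "kept"
            kept.append((rid, tseq, tqual))
        log_rows.append((rid, len(seq), len(tseq), disposition))
    log = pd.DataFrame(log_rows,
                       columns=["read_id", "input_len", "output_len", "disposition"])
    return kept, log


# -- FASTQ I/O ---------------------------------------------------------------

def _open(path: Union[str, Path], mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: Union[str, Path]) -> Iterator[FastqRecord]:
    with _open(path, "r") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(records: Iterable[FastqRecord], path: Union[str, Path]) -> None:
    with _open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
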