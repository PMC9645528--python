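"""Synthetic small RNA-seq data with planted biogenesis defects.

Generates a toy genome, a miRBase-dialect annotation and per-replicate
aligned reads (SAM, optionally raw FASTQ in the NEXTflex 4N + adapter
layout) whose statistical structure mirrors multi-replicate wild-type vs
mutant small RNA libraries:

* canonical miRNA hairpins with per-locus log-normal expression, negative
  binomial replicate noise, a configurable 3p arm fraction, categorical
  5'/3' isomiR offset distributions per condition, and a configurable
  fraction of partially processed (5' boundary -> one nt before the 3p 5'
  cleavage point) fragments;
* mirtron-like loci with extended stems and larger loops;
* inverted-repeat loci that emit 21–23 nt siRNA-like reads and carry no
  miRNA annotation (cluster-calling sources);
* duplicated loci with identical sequence whose reads map to both copies
  and are reported with hit count NH=2 (fractional-counting sources).

Every draw comes from one seeded generator per (config, condition,
replicate), so outputs are bit-reproducible; a truth table records what
was planted for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .annotation import write_gff3
from .hairpin import HairpinLocus, reverse_complement
from .intervals import GenomicInterval
from .quantify import AlignedRead
from .trim import ADAPTER3

DNA = "ACGT"
_RC = str.maketrans("ACGT", "TGCA")

CONDITIONS = ("wt", "mutant")

#: 3' adapter appended to raw reads (the 4 leading N are random bases).
ADAPTER3_FIXED = ADAPTER3.lstrip("N")  # TGGAATTCTCGGGTGCCAAGG


def _rc_dna(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass
class SimConfig:
    """Study-scale defaults: 20 loci, 3 replicates per genotype, 10^4 reads
    per replicate, and a mutant with shifted 3p 5' ends plus an elevated
    partial-cleavage fraction."""

    n_loci: int = 20
    n_replicates: int = 3
    library_size: int = 10_000
    expr_mu: float = 0.0
    expr_sigma: float = 1.0
    nb_dispersion: float = 0.1          # 0 => Poisson replicate noise
    arm_ratio: float = 0.5              # fraction of mature reads from 3p
    offset5p: Dict[str, Dict[int, float]] = field(default_factory=lambda: {
        "wt": {0: 1.0}, "mutant": {0: 1.0},
    })
    offset3p: Dict[str, Dict[int, float]] = field(default_factory=lambda: {
        "wt": {-1: 0.05, 0: 0.90, 1: 0.05},
        "mutant": {-1: 0.05, 0: 0.55, 1: 0.05, 2: 0.35},
    })
    partial_fraction: Dict[str, float] = field(default_factory=lambda: {
        "wt": 0.05, "mutant": 0.15,
    })
    read_len_dist: Dict[int, float] = field(default_factory=lambda: {
        19: 0.02, 20: 0.06, 21: 0.15, 22: 0.54, 23: 0.15, 24: 0.06, 25: 0.02,
    })
    canonical_stem: int = 22
    canonical_loop: int = 10
    mirtron_loci: int = 2
    mirtron_stem: Tuple[int, int] = (30, 35)
    mirtron_loop: Tuple[int, int] = (15, 20)
    cluster_loci: int = 2
    cluster_stem: int = 140
    cluster_loop: int = 20
    multimap_dup: int = 0
    #: canonical locus index -> expression multiplier in the mutant condition
    fold_change_loci: Dict[int, float] = field(default_factory=dict)
    spacing: int = 200
    chrom: str = "chrSim1"
    seed: int = 1

    def validate(self) -> None:
        for name, dist in (("offset5p", self.offset5p), ("offset3p", self.offset3p),
                           ("read_len_dist", {"": self.read_len_dist})):
            dists = dist.values() if name != "read_len_dist" else [self.read_len_dist]
            for d in dists:
                total = sum(d.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name} probabilities sum to {total}, not 1")
                if any(p < 0 for p in d.values()):
                    raise ValueError(f"{name} has negative probability")
        for cond, frac in self.partial_fraction.items():
            if not (0 <= frac <= 1):
                raise ValueError(f"partial_fraction[{cond}] outside [0,1]")
        if not (0 <= self.arm_ratio <= 1):
            raise ValueError("arm_ratio outside [0,1]")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class Reference:
    """Generated genome + annotation + planted truth."""

    genome: Dict[str, str]
    loci: List[HairpinLocus]             # annotated miRNA loci (incl. mirtrons)
    cluster_sources: List[GenomicInterval]
    truth: pd.DataFrame                  # one row per generated locus
    config: SimConfig

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        with open(fasta, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        gff = outdir / "annotation.gff3"
        write_gff3(self.loci, gff)
        truth = outdir / "truth_loci.tsv"
        self.truth.to_csv(truth, sep="\t", index=False)
        return {"fasta": fasta, "gff3": gff, "truth": truth}


@dataclass
class SimRead:
    """One simulated read with full provenance."""

    read_id: str
    locus_id: str
    category: str                        # miRNA_5p / miRNA_3p / partial_5prime_fragment / cluster
    insert: str                          # read sequence, 5'->3' (DNA letters)
    alignments: List[GenomicInterval]
    n_hits: int
    local_start: int
    local_end: int


@dataclass
class ReadSet:
    condition: str
    replicate: int
    reads: List[SimRead]
    config: SimConfig

    @property
    def sample(self) -> str:
        return f"{self.condition}_rep{self.replicate + 1}"

    def to_aligned_reads(self) -> List[AlignedRead]:
        return [
            AlignedRead(r.read_id, self.sample, len(r.insert),
                        r.alignments, r.n_hits)
            for r in self.reads
        ]

    def write_sam(self, path: Union[str, Path], genome: Dict[str, str]) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in sorted(genome.items())],
        }
        refs = {c: i for i, c in enumerate(sorted(genome))}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for r in self.reads:
                for aln in r.alignments:
                    seg = pysam.AlignedSegment(out.header)
                    seg.query_name = r.read_id
                    seg.reference_id = refs[aln.chrom]
                    seg.reference_start = aln.start
                    seg.cigarstring = f"{len(r.insert)}M"
                    seg.flag = 16 if aln.strand == "-" else 0
                    seg.mapping_quality = 255
                    fwd = genome[aln.chrom][aln.start:aln.end]
                    seg.query_sequence = fwd
                    seg.query_qualities = pysam.qualitystring_to_array(
                        "I" * len(fwd))
                    seg.set_tag("NH", r.n_hits)
                    out.write(seg)

    def write_fastq(self, path: Union[str, Path], rng: np.random.Generator) -> None:
        """NEXTflex layout: 4 random bases + insert + 4 random bases + adapter."""
        with open(path, "w") as fh:
            for r in self.reads:
                left = "".join(rng.choice(list(DNA), size=4))
                right = "".join(rng.choice(list(DNA), size=4))
                seq = left + r.insert + right + ADAPTER3_FIXED
                fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "read_id": r.read_id, "locus": r.locus_id,
                "category": r.category, "insert": r.insert,
                "n_hits": r.n_hits, "local_start": r.local_start,
                "local_end": r.local_end,
                "chrom": r.alignments[0].chrom,
                "start": r.alignments[0].start, "end": r.alignments[0].end,
                "strand": r.alignments[0].strand,
            }
            for r in self.reads
        ])


# -- reference construction ---------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def _hairpin_dna(rng: np.random.Generator, stem: int, loop: int) -> str:
    """Perfect inverted repeat: arm + loop + revcomp(arm); the loop's first
    and last bases are fixed non-complementary (G...A) so contiguous
    pairing stops exactly at the built stem."""
    arm = _random_seq(rng, stem)
    inner = _random_seq(rng, max(loop - 2, 0))
    loop_seq = ("G" + inner + "A")[:loop] if loop >= 2 else "G"[:loop]
    return arm + loop_seq + _rc_dna(arm)


def simulate_reference(cfg: SimConfig) -> Reference:
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    loci: List[HairpinLocus] = []
    cluster_sources: List[GenomicInterval] = []
    truth_rows = []
    pieces: List[str] = []
    pos = 0
    chrom = cfg.chrom
    arm_len = 22

    def _place(dna: str, strand: str) -> GenomicInterval:
        nonlocal pos
        gap = cfg.spacing + int(rng.integers(0, 100))
        pieces.append(_random_seq(rng, gap))
        pos += gap
        start = pos
        pieces.append(dna if strand == "+" else _rc_dna(dna))
        pos += len(dna)
        return GenomicInterval(chrom, start, pos, strand)

    n_dup = min(cfg.multimap_dup, cfg.n_loci)
    dup_dna: List[Tuple[str, str]] = []   # (source locus id, dna)

    for i in range(cfg.n_loci):
        stem = max(cfg.canonical_stem, arm_len)
        dna = _hairpin_dna(rng, stem, cfg.canonical_loop)
        strand = "+" if rng.random() < 0.5 else "-"
        iv = _place(dna, strand)
        L = len(dna)
        lid = f"sim-mir-{i + 1}"
        h = HairpinLocus(
            id=lid, interval=iv, sequence=dna if strand == "+" else dna,
            mature5p=(1, arm_len), mature3p=(L - arm_len + 1, L),
        )
        # sequence attribute must be the hairpin sense sequence
        h.sequence = h.sequence  # already sense: dna is the hairpin sense
        h.name5p, h.name3p = f"{lid}-5p", f"{lid}-3p"
        loci.append(h)
        expr = float(rng.lognormal(cfg.expr_mu, cfg.expr_sigma))
        group = f"dupgroup-{i + 1}" if i < n_dup else ""
        truth_rows.append(dict(
            locus=lid, kind="canonical", chrom=chrom, start=iv.start,
            end=iv.end, strand=strand, stem=stem, loop=cfg.canonical_loop,
            expression=expr, arm_ratio=cfg.arm_ratio,
            multimap_group=group, is_cluster_source=False,
            mutant_fold=float(cfg.fold_change_loci.get(i, 1.0)),
        ))
        if i < n_dup:
            dup_dna.append((lid, dna))

    for j, (src, dna) in enumerate(dup_dna):
        iv = _place(dna, "+")
        L = len(dna)
        lid = f"sim-mir-dup-{j + 1}"
        h = HairpinLocus(id=lid, interval=iv, sequence=dna,
                         mature5p=(1, arm_len), mature3p=(L - arm_len + 1, L))
        h.name5p, h.name3p = f"{lid}-5p", f"{lid}-3p"
        loci.append(h)
        truth_rows.append(dict(
            locus=lid, kind="duplicate", chrom=chrom, start=iv.start,
            end=iv.end, strand="+", stem=max(cfg.canonical_stem, arm_len),
            loop=cfg.canonical_loop, expression=0.0, arm_ratio=cfg.arm_ratio,
            multimap_group=f"dupgroup-{j + 1}", is_cluster_source=False,
        ))

    for m in range(cfg.mirtron_loci):
        stem = int(rng.integers(cfg.mirtron_stem[0], cfg.mirtron_stem[1] + 1))
        loop = int(rng.integers(cfg.mirtron_loop[0], cfg.mirtron_loop[1] + 1))
        dna = _hairpin_dna(rng, stem, loop)
        strand = "+" if rng.random() < 0.5 else "-"
        iv = _place(dna, strand)
        L = len(dna)
        lid = f"sim-mirtron-{m + 1}"
        h = HairpinLocus(id=lid, interval=iv, sequence=dna,
                         mature5p=(1, arm_len), mature3p=(L - arm_len + 1, L),
                         is_mirtron=True)
        h.name5p, h.name3p = f"{lid}-5p", f"{lid}-3p"
        loci.append(h)
        expr = float(rng.lognormal(cfg.expr_mu, cfg.expr_sigma))
        truth_rows.append(dict(
            locus=lid, kind="mirtron", chrom=chrom, start=iv.start, end=iv.end,
            strand=strand, stem=stem, loop=loop, expression=expr,
            arm_ratio=cfg.arm_ratio, multimap_group="",
            is_cluster_source=False,
        ))

    for c in range(cfg.cluster_loci):
        dna = _hairpin_dna(rng, cfg.cluster_stem, cfg.cluster_loop)
        iv = _place(dna, "+")
        lid = f"sim-cluster-{c + 1}"
        cluster_sources.append(iv)
        expr = float(rng.lognormal(cfg.expr_mu, cfg.expr_sigma))
        truth_rows.append(dict(
            locus=lid, kind="cluster", chrom=chrom, start=iv.start, end=iv.end,
            strand="+", stem=cfg.cluster_stem, loop=cfg.cluster_loop,
            expression=expr, arm_ratio=np.nan, multimap_group="",
            is_cluster_source=True,
        ))

    pieces.append(_random_seq(rng, cfg.spacing))
    genome = {chrom: "".join(pieces)}

    # fix hairpin sense sequences for minus-strand loci
    for h, row in zip(loci, (r for r in truth_rows if r["kind"] != "cluster")):
        iv = h.interval
        sense = genome[chrom][iv.start:iv.end]
        if iv.strand == "-":
            sense = _rc_dna(sense)
        h.sequence = sense.replace("T", "U")

    truth = pd.DataFrame(truth_rows)
    if "mutant_fold" not in truth.columns:
        truth["mutant_fold"] = 1.0
    truth["mutant_fold"] = truth["mutant_fold"].fillna(1.0)
    expr_total = truth.loc[truth["kind"].isin(["canonical", "mirtron", "cluster"]),
                           "expression"].sum()
    truth["expected_fraction"] = truth["expression"] / expr_total
    truth["expected_count"] = truth["expected_fraction"] * cfg.library_size
    for cond in CONDITIONS:
        off = cfg.offset3p.get(cond, {0: 1.0})
        modal = max(sorted(off), key=lambda k: (off[k], -abs(k)))
        truth[f"modal_offset3p_{cond}"] = np.where(
            truth["kind"] == "cluster", np.nan, modal)
        truth[f"partial_fraction_{cond}"] = np.where(
            truth["kind"] == "cluster", np.nan,
            cfg.partial_fraction.get(cond, 0.0))
    return Reference(genome=genome, loci=loci, cluster_sources=cluster_sources,
                     truth=truth, config=cfg)


# -- read generation ----------------------------------------------------------


def _draw_categorical(rng: np.random.Generator, dist: Dict[int, float],
                      size: int) -> np.ndarray:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return np.asarray(keys)[rng.choice(len(keys), size=size, p=probs)]


def simulate_reads(ref: Reference, cfg: SimConfig, condition: str,
                   replicate: int) -> ReadSet:
    """Draw one replicate library for one condition.

    A single seeded stream per (seed, condition, replicate) drives, in
    order: per-locus NB counts, then per-read category, arm, offsets and
    lengths locus by locus.
    """
    if condition not in cfg.offset3p and condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = CONDITIONS.index(condition) if condition in CONDITIONS else 99
    rng = np.random.default_rng([cfg.seed, 1 + cond_idx, replicate])

    loci_by_id = {h.id: h for h in ref.loci}
    truth = ref.truth
    emitting = truth[truth["kind"].isin(["canonical", "mirtron", "cluster"])]
    dup_partner: Dict[str, str] = {}
    dups = truth[truth["multimap_group"] != ""]
    for grp, sub in dups.groupby("multimap_group"):
        ids = list(sub["locus"])
        if len(ids) == 2:
            dup_partner[ids[0]] = ids[1]
            dup_partner[ids[1]] = ids[0]

    reads: List[SimRead] = []
    counter = 0
    off3 = cfg.offset3p.get(condition, {0: 1.0})
    off5 = cfg.offset5p.get(condition, {0: 1.0})
    pfrac = cfg.partial_fraction.get(condition, 0.0)

    for _, row in emitting.iterrows():
        mu = row["expected_count"]
        if condition == "mutant":
            fold = row.get("mutant_fold", 1.0)
            if pd.notna(fold):
                mu = mu * float(fold)
        if cfg.nb_dispersion > 0:
            r_nb = 1.0 / cfg.nb_dispersion
            p_nb = r_nb / (r_nb + mu) if mu > 0 else 1.0
            n_reads = int(rng.negative_binomial(r_nb, p_nb)) if mu > 0 else 0
        else:
            n_reads = int(rng.poisson(mu))
        if n_reads == 0:
            continue
        lid = row["locus"]
        if row["kind"] == "cluster":
            iv = GenomicInterval(row["chrom"], int(row["start"]),
                                 int(row["end"]), row["strand"])
            lens = 21 + rng.integers(0, 3, size=n_reads)
            starts = rng.integers(0, iv.length - 25, size=n_reads)
            for ln, st in zip(lens, starts):
                gs = iv.start + int(st)
                insert = ref.genome[iv.chrom][gs:gs + int(ln)]
                counter += 1
                reads.append(SimRead(
                    read_id=f"{condition}_r{replicate + 1}_{counter}",
                    locus_id=lid, category="cluster", insert=insert,
                    alignments=[GenomicInterval(iv.chrom, gs, gs + int(ln), "+")],
                    n_hits=1, local_start=int(st) + 1, local_end=int(st + ln),
                ))
            continue

        h = loci_by_id[lid]
        L = len(h.sequence)
        is_partial = rng.random(n_reads) < pfrac
        is_3p = rng.random(n_reads) < row["arm_ratio"]
        offs3 = _draw_categorical(rng, off3, n_reads)
        offs5 = _draw_categorical(rng, off5, n_reads)
        lens = _draw_categorical(rng, cfg.read_len_dist, n_reads)
        partner = dup_partner.get(lid)
        for k in range(n_reads):
            if is_partial[k]:
                lo, hi = 1, h.cp_3p5 - 1
                category = "partial_5prime_fragment"
            elif is_3p[k]:
                lo = int(np.clip(h.cp_3p5 + offs3[k], 1, L))
                hi = int(min(L, lo + lens[k] - 1))
                category = "miRNA_3p"
            else:
                hi = int(np.clip(h.cp_5p3 - offs5[k], 1, L))
                lo = int(max(1, hi - lens[k] + 1))
                category = "miRNA_5p"
            insert_rna = h.sequence[lo - 1:hi]
            insert = insert_rna.replace("U", "T")
            gs, ge = h.local_to_genomic(lo, hi)
            alns = [GenomicInterval(h.interval.chrom, gs, ge, h.interval.strand)]
            n_hits = 1
            if partner is not None:
                ph = loci_by_id[partner]
                pgs, pge = ph.local_to_genomic(lo, hi)
                alns.append(GenomicInterval(ph.interval.chrom, pgs, pge,
                                            ph.interval.strand))
                n_hits = 2
            counter += 1
            reads.append(SimRead(
                read_id=f"{condition}_r{replicate + 1}_{counter}",
                locus_id=lid, category=category, insert=insert,
                alignments=alns, n_hits=n_hits, local_start=lo, local_end=hi,
            ))
    return ReadSet(condition=condition, replicate=replicate, reads=reads,
                   config=cfg)


def simulate_condition(ref: Reference, cfg: SimConfig,
                       condition: str) -> List[ReadSet]:
    return [simulate_reads(ref, cfg, condition, r)
            for r in range(cfg.n_replicates)]


def write_condition(ref: Reference, readsets: Sequence[ReadSet],
                    outdir: Union[str, Path],
                    fastq: bool = True) -> Dict[str, List[Path]]:
    """Write SAM + FASTQ + per-read truth TSV for each replicate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, List[Path]] = {"sam": [], "fastq": [], "truth": []}
    for rs in readsets:
        stem = outdir / rs.sample
        sam = stem.with_suffix(".sam")
        rs.write_sam(sam, ref.genome)
        paths["sam"].append(sam)
        if fastq:
            cond_idx = CONDITIONS.index(rs.condition) if rs.condition in CONDITIONS else 99
            fq_rng = np.random.default_rng(
                [rs.config.seed, 1000 + cond_idx, rs.replicate])
            fq = stem.with_suffix(".fastq")
            rs.write_fastq(fq, fq_rng)
            paths["fastq"].append(fq)
        truth = Path(str(stem) + "_truth.tsv")
        rs.truth_frame().to_csv(truth, sep="\t", index=False)
        paths["truth"].append(truth)
    return paths
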