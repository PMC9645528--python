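"""miRBase-dialect GFF3 / FASTA parsing into :class:`HairpinLocus` objects.

The annotation dialect uses ``miRNA_primary_transcript`` features for
hairpins and ``miRNA`` features for mature arms; a mature names its hairpin
via the ``Derives_from`` attribute (falling back to a hairpin-name prefix
of its ``Name``). GFF3 coordinates are 1-based inclusive and are converted
to the package-internal 0-based half-open system here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Union

import gffutils
from Bio import SeqIO

from .hairpin import HairpinLocus, as_rna, reverse_complement
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

PRIMARY_TYPE = "miRNA_primary_transcript"
MATURE_TYPE = "miRNA"


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Load sequences keyed by record id (DNA kept as-is)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _attr(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def parse_annotation(
    gff3: Union[str, Path],
    fasta: Union[str, Path, Dict[str, str]],
    mirtron_ids: Optional[Set[str]] = None,
) -> List[HairpinLocus]:
    """Parse hairpin loci with precursor-local mature arms and cleavage points.

    Records that violate the dialect (mature outside its hairpin, hairpin on
    a sequence absent from the FASTA) are rejected with a logged diagnostic
    rather than aborting the whole parse.
    """
    genome = fasta if isinstance(fasta, dict) else read_fasta(fasta)
    mirtron_ids = mirtron_ids or set()

    db = gffutils.create_db(
        str(gff3), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    hairpins: Dict[str, HairpinLocus] = {}
    order: List[str] = []
    for f in db.features_of_type(PRIMARY_TYPE):
        hid = _attr(f, "ID") or _attr(f, "Name") or f.id
        name = _attr(f, "Name") or hid
        if f.seqid not in genome:
            log.warning("hairpin %s: sequence %s missing from FASTA; rejected",
                        hid, f.seqid)
            continue
        chrom_seq = genome[f.seqid]
        start, end = f.start - 1, f.end  # GFF3 1-based inclusive -> half-open
        if end > len(chrom_seq):
            log.warning("hairpin %s: extends past end of %s; rejected", hid, f.seqid)
            continue
        dna = chrom_seq[start:end]
        rna = as_rna(dna)
        if f.strand == "-":
            rna = reverse_complement(rna)
        interval = GenomicInterval(f.seqid, start, end, f.strand)
        hairpins[hid] = HairpinLocus(
            id=name, interval=interval, sequence=rna,
            is_mirtron=(name in mirtron_ids or hid in mirtron_ids),
        )
        hairpins[hid].name5p = None
        order.append(hid)

    for f in db.features_of_type(MATURE_TYPE):
        mname = _attr(f, "Name") or _attr(f, "ID") or f.id
        hid = _attr(f, "Derives_from")
        if hid is None or hid not in hairpins:
            # fall back: hairpin whose name prefixes the mature name
            matches = [k for k, h in hairpins.items()
                       if mname.startswith(h.id) or mname.startswith(k)]
            if len(matches) == 1:
                hid = matches[0]
            else:
                log.warning("mature %s: no unique hairpin (Derives_from=%s); "
                            "rejected", mname, hid)
                continue
        h = hairpins[hid]
        try:
            lo, hi = h.genomic_to_local(f.start - 1, f.end)
        except ValueError as exc:
            log.warning("mature %s outside hairpin %s: %s; rejected",
                        mname, h.id, exc)
            continue
        # arm assignment: explicit -5p/-3p suffix wins; otherwise position
        if mname.endswith("5p"):
            arm = "5p"
        elif mname.endswith("3p"):
            arm = "3p"
        else:
            arm = "5p" if lo - 1 < len(h.sequence) - hi else "3p"
        if arm == "5p":
            h.mature5p, h.name5p = (lo, hi), mname
        else:
            h.mature3p, h.name3p = (lo, hi), mname

    out: List[HairpinLocus] = []
    for hid in order:
        h = hairpins[hid]
        if h.mature5p and h.mature3p:
            h.cp_5p3 = h.mature5p[1]
            h.cp_3p5 = h.mature3p[0]
        out.append(h)
    return out


def mature_features(loci: Iterable[HairpinLocus]):
    """Flatten loci into (feature_name, GenomicInterval, hairpin_id, arm)
    rows for the mature arms — the counting unit of the expression module."""
    rows = []
    for h in loci:
        for arm, mat, name in (("5p", h.mature5p, h.name5p),
                               ("3p", h.mature3p, h.name3p)):
            if mat is None:
                continue
            gs, ge = h.local_to_genomic(*mat)
            rows.append((
                name or f"{h.id}-{arm}",
                GenomicInterval(h.interval.chrom, gs, ge, h.interval.strand),
                h.id,
                arm,
            ))
    return rows


def write_gff3(loci: Iterable[HairpinLocus], path: Union[str, Path]) -> None:
    """Emit the miRBase dialect consumed by :func:`parse_annotation`."""
    lines = ["##gff-version 3"]
    for h in loci:
        iv = h.interval
        lines.append("\t".join([
            iv.chrom, "mirproc", PRIMARY_TYPE, str(iv.start + 1), str(iv.end),
            ".", iv.strand, ".", f"ID={h.id};Name={h.id}",
        ]))
        for arm, mat in (("5p", h.mature5p), ("3p", h.mature3p)):
            if mat is None:
                continue
            gs, ge = h.local_to_genomic(*mat)
            name = (h.name5p if arm == "5p" else h.name3p) or f"{h.id}-{arm}"
            lines.append("\t".join([
                iv.chrom, "mirproc", MATURE_TYPE, str(gs + 1), str(ge),
                ".", iv.strand, ".",
                f"ID={name};Name={name};Derives_from={h.id}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")
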