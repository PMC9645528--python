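"""Cleave a published pre-miRNA and fold the published tetraloop substrates.

Demonstrates the hairpin-geometry model on real oligonucleotide sequences:
the 59-nt mouse pre-miR-15a cleaved at its two Dicer scissile positions,
and the two perfect-duplex GCAA-tetraloop binding substrates.
"""

from mirproc.hairpin import cleave_hairpin, fold_stem
from mirproc.sequences import (PRE_MIR_15A, PRE_MIR_15A_CUT3,
                               PRE_MIR_15A_CUT5, STEMLOOP_30BP, STEMLOOP_42BP)

product = cleave_hairpin(PRE_MIR_15A, PRE_MIR_15A_CUT5, PRE_MIR_15A_CUT3)
print(f"pre-miR-15a ({len(PRE_MIR_15A)} nt), cut after position "
      f"{PRE_MIR_15A_CUT5} and before position {PRE_MIR_15A_CUT3}:")
print(f"  5p strand  {product.strand5p}  ({product.duplex_len5p} nt)")
print(f"  loop       {product.loop}  ({len(product.loop)} nt)")
print(f"  3p strand  {product.strand3p}  ({product.duplex_len3p} nt)")
print("The two cuts release a 22-nt miRNA duplex (5p + 3p strands) and a "
      "15-nt terminal loop.\n")

for name, seq in (("30bp stem-loop", STEMLOOP_30BP),
                  ("42bp stem-loop", STEMLOOP_42BP)):
    geo = fold_stem(seq)
    print(f"{name} ({len(seq)} nt): stem {geo.stem_len} bp, "
          f"loop {geo.loop_len} nt, 3' overhang {geo.overhang3} nt")
print("Both substrates are perfect Watson-Crick duplexes capped by a GCAA "
      "tetraloop with a 2-nt 3' UU overhang.")
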