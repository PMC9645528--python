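"""Generate a synthetic two-genotype experiment and recover what was planted.

Builds a toy genome with annotated miRNA hairpins, simulates wild-type and
mutant small RNA libraries (3 replicates each), then runs the counting,
normalization and partial-processing modules and compares their output to
the generator's truth table.
"""

import numpy as np

from mirproc.annotation import mature_features
from mirproc.partial import categorize_by_locus, partial_fraction_table
from mirproc.quantify import base_mean_and_lfc, count_features
from mirproc.simulate import SimConfig, simulate_condition, simulate_reference

cfg = SimConfig(n_loci=10, n_replicates=3, library_size=10_000,
                mirtron_loci=0, cluster_loci=0,
                partial_fraction={"wt": 0.05, "mutant": 0.15},
                fold_change_loci={0: 4.0}, seed=42)
ref = simulate_reference(cfg)
readsets = {c: simulate_condition(ref, cfg, c) for c in ("wt", "mutant")}

feats = [(n, iv) for n, iv, _, _ in mature_features(ref.loci)]
samples = {rs.sample: rs.to_aligned_reads()
           for c in readsets for rs in readsets[c]}
table = count_features(samples, feats)
stats = base_mean_and_lfc(table, ([rs.sample for rs in readsets["wt"]],
                                  [rs.sample for rs in readsets["mutant"]]))

print(f"{len(ref.loci)} loci, {int(table.counts.sum().sum())} counted reads "
      f"across {len(samples)} libraries")
print(f"planted 4x locus sim-mir-1: recovered log2FC "
      f"{stats.loc['sim-mir-1-3p', 'log2fc']:+.2f} (planted +2.00)")
print(f"unchanged locus sim-mir-2: recovered log2FC "
      f"{stats.loc['sim-mir-2-3p', 'log2fc']:+.2f} (planted +0.00)")

tables = {c: categorize_by_locus(
    [r for rs in readsets[c] for r in rs.to_aligned_reads()], ref.loci)
    for c in readsets}
summary = partial_fraction_table(tables, contrast=("wt", "mutant"))
print(f"partial 5'-fragment percentage, pooled over loci: "
      f"wt {np.nanmean(summary['wt']):.1f}% (planted 5%), "
      f"mutant {np.nanmean(summary['mutant']):.1f}% (planted 15%)")
print("-> higher partial-fragment share in the mutant marks asymmetric "
      "single-cut processing at the 5' end of the 3p miRNA.")
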