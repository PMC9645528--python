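"""Guide / passenger (miRNA / miRNA*) strand sorting.

Of the two strands of the Dicer-produced duplex, the guide ("miRNA") is
preferentially loaded onto AGO while the passenger ("miRNA*") is degraded.
This module assigns those labels from expression data by a fixed six-rule
procedure applied in order:

1. mature miRNAs are paired by their hairpin; each arm carries a baseMean
   per experiment;
2. pairs with complete external miRNA/miRNA* type annotation are kept as-is;
3. a lone annotated mature is ``single_miRNA``;
4. if both baseMeans are below 0.25 the pair is ``lowExp``;
5. if one baseMean is at least double the other, the higher arm is
   ``miRNA`` and the lower ``miRNA*``; otherwise ``notClear``;
6. across experiments, a miRNA <-> miRNA* disagreement for the same arm is
   ``cellSpecific``; any other disagreement is ``notClear``.

"At least double" is taken literally as >= 2x (a ratio of exactly 2 is
decisive; a ratio of exactly 1 is ``notClear``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

LABELS = ("miRNA", "miRNA*", "single_miRNA", "lowExp", "notClear", "cellSpecific")

LOW_EXP_THRESHOLD = 0.25
DOMINANCE_RATIO = 2.0


def _classify_pair_one_experiment(bm5: float, bm3: float,
                                  low_exp: float, ratio: float):
    if bm5 < low_exp and bm3 < low_exp:
        return "lowExp", "lowExp"
    if bm5 >= ratio * bm3:
        return "miRNA", "miRNA*"
    if bm3 >= ratio * bm5:
        return "miRNA*", "miRNA"
    return "notClear", "notClear"


def _combine(labels: Sequence[str]) -> str:
    uniq = set(labels)
    if len(uniq) == 1:
        return labels[0]
    if uniq == {"miRNA", "miRNA*"}:
        return "cellSpecific"
    return "notClear"


def classify_pairs(
    features: pd.DataFrame,
    experiments: Sequence[str],
    low_exp: float = LOW_EXP_THRESHOLD,
    dominance: float = DOMINANCE_RATIO,
) -> pd.DataFrame:
    """Label every annotated mature arm.

    ``features`` needs columns ``feature``, ``hairpin``, ``arm`` (5p/3p) and
    one ``base_mean_<experiment>`` column per experiment; an optional
    ``annotated_type`` column (values miRNA / miRNA*) activates rule 2.
    Returns the input plus per-experiment ``label_<experiment>`` columns and
    a final ``label`` column. Features without a hairpin assignment are
    excluded and reported in the ``unpaired`` attribute of the result.
    """
    df = features.copy()
    unpaired = df[df["hairpin"].isna()] if df["hairpin"].isna().any() else df.iloc[0:0]
    df = df[df["hairpin"].notna()].copy()
    # deterministic regardless of input order
    df = df.sort_values(["hairpin", "arm", "feature"], kind="mergesort")

    for e in experiments:
        df[f"label_{e}"] = ""
    df["label"] = ""

    for _, idx in df.groupby("hairpin").groups.items():
        sub = df.loc[idx]
        if len(sub) == 1:
            df.loc[idx, [f"label_{e}" for e in experiments]] = "single_miRNA"
            df.loc[idx, "label"] = "single_miRNA"
            continue
        arms = {row["arm"]: i for i, row in sub.iterrows()}
        i5, i3 = arms.get("5p"), arms.get("3p")
        if i5 is None or i3 is None:  # two matures on one arm: treat first as 5p-like
            i5, i3 = list(sub.index)[:2]
        if "annotated_type" in sub.columns:
            types = set(sub["annotated_type"].dropna())
            if types == {"miRNA", "miRNA*"}:
                for e in experiments:
                    df.loc[i5, f"label_{e}"] = df.loc[i5, "annotated_type"]
                    df.loc[i3, f"label_{e}"] = df.loc[i3, "annotated_type"]
                df.loc[i5, "label"] = df.loc[i5, "annotated_type"]
                df.loc[i3, "label"] = df.loc[i3, "annotated_type"]
                continue
        for e in experiments:
            l5, l3 = _classify_pair_one_experiment(
                df.loc[i5, f"base_mean_{e}"], df.loc[i3, f"base_mean_{e}"],
                low_exp, dominance,
            )
            df.loc[i5, f"label_{e}"] = l5
            df.loc[i3, f"label_{e}"] = l3
        for i in (i5, i3):
            df.loc[i, "label"] = _combine(
                [df.loc[i, f"label_{e}"] for e in experiments])

    df.attrs["unpaired"] = list(unpaired["feature"]) if len(unpaired) else []
    return df


def ma_table(
    classified: pd.DataFrame,
    stats: pd.DataFrame,
    subset: str = "all",
    mirtron_ids: Optional[Set[str]] = None,
    significant: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """MA-plot table (baseMean vs log2 fold change) for a label subset.

    ``subset``: ``dominant`` keeps arms labeled miRNA, ``passenger`` keeps
    miRNA*, ``all`` keeps every arm present in ``stats``. ``stats`` is the
    per-feature frame from :func:`mirproc.quantify.base_mean_and_lfc`.
    """
    if subset not in ("dominant", "passenger", "all"):
        raise ValueError(f"unknown subset {subset!r}")
    df = classified.set_index("feature")
    keep = df.index
    if subset == "dominant":
        keep = df.index[df["label"] == "miRNA"]
    elif subset == "passenger":
        keep = df.index[df["label"] == "miRNA*"]
    keep = [f for f in keep if f in stats.index]
    out = pd.DataFrame({
        "base_mean": stats.loc[keep, "base_mean"],
        "log2fc": stats.loc[keep, "log2fc"],
        "arm": df.loc[keep, "arm"],
        "label": df.loc[keep, "label"],
    })
    out["significant"] = (significant.reindex(keep)
                          if significant is not None else pd.NA)
    mirtron_ids = mirtron_ids or set()
    out["is_mirtron"] = [
        (df.loc[f, "hairpin"] in mirtron_ids) or (f in mirtron_ids) for f in keep
    ]
    return out
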