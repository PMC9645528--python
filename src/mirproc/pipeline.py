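"""End-to-end pipeline orchestration with a structured config and manifest.

``RunConfig`` mirrors each analysis module's parameters (every default is
the published pipeline's printed value), plus paths and a seed. Stages are
run in dependency order; each run writes a ``manifest.json`` recording the
effective config, its hash, the seed and every output file, so reruns with
an identical config are byte-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import __version__
from .annotation import mature_features, parse_annotation, read_fasta
from .classify import classify_pairs
from .clusters import (annotate_clusters, call_clusters_replicate,
                       consolidate_genotype, write_bed)
from .fidelity import BASE_MEAN_GATE, collect_end_profiles, fidelity_matrix, select_and_order
from .partial import categorize_by_locus, partial_fraction_table
from .quantify import base_mean_and_lfc, count_features, reads_from_sam, size_factors
from .simulate import CONDITIONS, SimConfig, simulate_condition, simulate_reference, write_condition
from .trim import TrimConfig, read_fastq, trim_reads, write_fastq

log = logging.getLogger(__name__)

STAGES = ("simulate", "trim", "count", "classify", "clusters", "fidelity", "partial")

#: stage -> stages that must have run (or have outputs present) first
DEPENDENCIES = {
    "trim": ("simulate",),
    "count": ("simulate",),
    "classify": ("count",),
    "clusters": ("simulate",),
    "fidelity": ("count",),
    "partial": ("simulate",),
}


@dataclass
class RunConfig:
    outdir: str = "mirproc_out"
    seed: int = 1
    log_level: str = "INFO"
    simulate: Dict = field(default_factory=dict)     # SimConfig overrides
    trim: Dict = field(default_factory=dict)         # TrimConfig overrides
    count: Dict = field(default_factory=lambda: {
        "min_overlap": 15, "length_range": [19, 25], "pseudocount": 0.5,
    })
    classify: Dict = field(default_factory=lambda: {
        "low_exp": 0.25, "dominance": 2.0,
    })
    clusters: Dict = field(default_factory=lambda: {
        "rpm_min": 3.0, "join_dist": 50, "length_range": [21, 23],
    })
    fidelity: Dict = field(default_factory=lambda: {
        "window": 15, "max_shift": 7, "flank": 5, "k": 50,
        "base_mean_gate": 100.0,
    })
    partial: Dict = field(default_factory=lambda: {"tolerance": 2})

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> SimConfig:
    kwargs = dict(cfg.simulate)
    kwargs.setdefault("seed", cfg.seed)
    for key in ("offset3p", "offset5p"):
        if key in kwargs:
            kwargs[key] = {c: {int(k): float(v) for k, v in d.items()}
                           for c, d in kwargs[key].items()}
    if "read_len_dist" in kwargs:
        kwargs["read_len_dist"] = {int(k): float(v)
                                   for k, v in kwargs["read_len_dist"].items()}
    if "fold_change_loci" in kwargs:
        kwargs["fold_change_loci"] = {int(k): float(v)
                                      for k, v in kwargs["fold_change_loci"].items()}
    if "mirtron_stem" in kwargs:
        kwargs["mirtron_stem"] = tuple(kwargs["mirtron_stem"])
    if "mirtron_loop" in kwargs:
        kwargs["mirtron_loop"] = tuple(kwargs["mirtron_loop"])
    return SimConfig(**kwargs)


def run_pipeline(cfg: RunConfig,
                 stages: Optional[Sequence[str]] = None) -> Dict:
    """Run the requested stages on the synthetic workflow; returns the manifest.

    Stage dependencies are enforced: a stage whose prerequisite neither ran
    in this invocation nor left outputs in ``outdir`` raises a
    ``RuntimeError`` naming the missing stage.
    """
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config_hash": cfg.hash(), "seed": cfg.seed,
        "version": __version__, "stages": stages, "outputs": {},
        "config": cfg.to_dict(),
    }
    done = set()
    state: Dict = {}

    def _require(stage: str) -> None:
        for dep in DEPENDENCIES.get(stage, ()):
            if dep in done or dep in state:
                continue
            if dep == "simulate" and (outdir / "annotation.gff3").exists():
                _load_simulated()
                continue
            if dep == "count" and (outdir / "counts.tsv").exists():
                _load_counts()
                continue
            raise RuntimeError(
                f"stage {stage!r} requires stage {dep!r} to have run first")

    def _load_simulated() -> None:
        sim_cfg = _sim_config(cfg)
        ref = simulate_reference(sim_cfg)      # reference is seed-reproducible
        readsets = {c: simulate_condition(ref, sim_cfg, c) for c in CONDITIONS}
        state["ref"], state["readsets"], state["sim_cfg"] = ref, readsets, sim_cfg
        state["simulate"] = True

    def _load_counts() -> None:
        if "ref" not in state:
            _load_simulated()
        if "count_stats" not in state:
            _run_count()
        done.add("count")

    def _run_count() -> None:
        ref, readsets = state["ref"], state["readsets"]
        p = cfg.count
        feats = [(n, iv) for n, iv, _, _ in mature_features(ref.loci)]
        reads_by_sample = {
            rs.sample: rs.to_aligned_reads()
            for cond in CONDITIONS for rs in readsets[cond]
        }
        table = count_features(
            reads_by_sample, feats, min_overlap=p.get("min_overlap", 15),
            length_range=tuple(p.get("length_range", (19, 25))),
        )
        wt = [rs.sample for rs in readsets["wt"]]
        mut = [rs.sample for rs in readsets["mutant"]]
        stats = base_mean_and_lfc(table, (wt, mut),
                                  pseudocount=p.get("pseudocount", 0.5))
        state["table"], state["count_stats"] = table, stats
        table.counts.to_csv(outdir / "counts.tsv", sep="\t")
        stats.to_csv(outdir / "expression_stats.tsv", sep="\t")
        manifest["outputs"]["count"] = ["counts.tsv", "expression_stats.tsv"]

    for stage in stages:
        if stage == "simulate":
            _load_simulated()
            ref, readsets = state["ref"], state["readsets"]
            paths = ref.write(outdir)
            outs = [str(p.name) for p in paths.values()]
            for cond in CONDITIONS:
                written = write_condition(ref, readsets[cond], outdir)
                outs += [p.name for ps in written.values() for p in ps]
            manifest["outputs"]["simulate"] = sorted(outs)

        elif stage == "trim":
            _require("trim")
            outs = []
            tcfg = TrimConfig(**cfg.trim)
            for fq in sorted(outdir.glob("*_rep*.fastq")):
                if fq.name.endswith(".trimmed.fastq"):
                    continue
                kept, disp = trim_reads(read_fastq(fq), tcfg)
                out_fq = fq.with_suffix(".trimmed.fastq")
                write_fastq(kept, out_fq)
                disp.to_csv(fq.with_suffix(".trimlog.tsv"), sep="\t", index=False)
                outs += [out_fq.name, fq.with_suffix(".trimlog.tsv").name]
            manifest["outputs"]["trim"] = outs

        elif stage == "count":
            _require("count")
            _run_count()

        elif stage == "classify":
            _require("classify")
            ref, readsets = state["ref"], state["readsets"]
            table = state["table"]
            p = cfg.classify
            rows = []
            for name, _, hid, arm in mature_features(ref.loci):
                rows.append({"feature": name, "hairpin": hid, "arm": arm})
            feats = pd.DataFrame(rows)
            norm = table.counts.div(table.size_factors, axis=1)
            wt = [rs.sample for rs in readsets["wt"]]
            mut = [rs.sample for rs in readsets["mutant"]]
            feats["base_mean_wt"] = norm[wt].mean(axis=1).reindex(feats["feature"]).values
            feats["base_mean_mutant"] = norm[mut].mean(axis=1).reindex(feats["feature"]).values
            labeled = classify_pairs(feats, ["wt", "mutant"],
                                     low_exp=p.get("low_exp", 0.25),
                                     dominance=p.get("dominance", 2.0))
            labeled.to_csv(outdir / "strand_labels.tsv", sep="\t", index=False)
            state["labels"] = labeled
            manifest["outputs"]["classify"] = ["strand_labels.tsv"]

        elif stage == "clusters":
            _require("clusters")
            ref, readsets = state["ref"], state["readsets"]
            p = cfg.clusters
            outs = []
            for cond in CONDITIONS:
                rep_sets = []
                for rs in readsets[cond]:
                    clusters = call_clusters_replicate(
                        rs.to_aligned_reads(), rpm_min=p.get("rpm_min", 3.0),
                        join_dist=p.get("join_dist", 50),
                        length_range=tuple(p.get("length_range", (21, 23))),
                    )
                    bed = outdir / f"clusters_{rs.sample}.bed"
                    write_bed(clusters, bed)
                    outs.append(bed.name)
                    rep_sets.append(clusters)
                genotype = consolidate_genotype(rep_sets)
                layers = {"miRNA": [h.interval for h in ref.loci]}
                genotype = annotate_clusters(genotype, layers)
                bed = outdir / f"clusters_{cond}.bed"
                write_bed(genotype, bed)
                outs.append(bed.name)
            manifest["outputs"]["clusters"] = outs

        elif stage == "fidelity":
            _require("fidelity")
            ref, readsets = state["ref"], state["readsets"]
            stats = state["count_stats"]
            p = cfg.fidelity
            gate = p.get("base_mean_gate", BASE_MEAN_GATE)
            expressed = set(stats.index[stats["base_mean"] >= gate])
            gated = [h for h in ref.loci
                     if {h.name5p, h.name3p} & expressed]
            profiles = {
                cond: collect_end_profiles(
                    [rs.to_aligned_reads() for rs in readsets[cond]],
                    gated, window=p.get("window", 15))
                for cond in CONDITIONS
            }
            diff = fidelity_matrix(profiles["mutant"], profiles["wt"],
                                   window=p.get("window", 15),
                                   flank=p.get("flank", 5),
                                   max_shift=p.get("max_shift", 7))
            top = select_and_order(diff, k=p.get("k", 50))
            diff.to_csv(outdir / "fidelity_diff.tsv", sep="\t")
            top.to_csv(outdir / "fidelity_top.tsv", sep="\t")
            state["fidelity"] = diff
            manifest["outputs"]["fidelity"] = ["fidelity_diff.tsv",
                                               "fidelity_top.tsv"]

        elif stage == "partial":
            _require("partial")
            ref, readsets = state["ref"], state["readsets"]
            tol = cfg.partial.get("tolerance", 2)
            tables = {}
            for cond in CONDITIONS:
                reads = [r for rs in readsets[cond] for r in rs.to_aligned_reads()]
                tables[cond] = categorize_by_locus(reads, ref.loci, tol=tol)
            summary = partial_fraction_table(tables, contrast=("wt", "mutant"))
            summary.to_csv(outdir / "partial_fractions.tsv", sep="\t")
            manifest["outputs"]["partial"] = ["partial_fractions.tsv"]

        done.add(stage)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    cfg.to_yaml(outdir / "effective_config.yaml")
    return manifest
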