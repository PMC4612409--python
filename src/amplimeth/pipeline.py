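"""End-to-end orchestration of the analysis stages from one configuration.

Stage order mirrors the study design: expression trend selection → CpG island
prediction → bisulfite read alignment and methylation calling → group
comparison and clustering → miRNA normalization → IHC Q-scores.  With the
``simulate`` stage enabled all inputs are generated synthetically with
planted truth; otherwise file paths must be supplied.  All randomness flows
from one global seed through named per-stage substreams, and every artifact
is a plain text table, so identical configurations produce byte-identical
report bundles.
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .align import ScoringScheme, align_read, filter_reads
from .cpg import predict_islands
from .ihc import summarize_qscores
from .methylation import (
    build_methylation_matrix,
    call_cpg_methylation,
    cluster_markers,
    compare_methylation_groups,
)
from .mirna import normalize_panel, compare_mirna_groups, rank_mirnas_by_targets
from .synthetic import (
    default_template,
    gen_bisulfite_reads,
    gen_ct_plates,
    gen_qscore_cores,
    gen_staged_expression,
)
from .trends import select_markers, trend_table, venn_categorize

__all__ = ["PipelineConfig", "PipelineConfigError", "validate_config", "run_pipeline"]

STAGE_NAMES = ("simulate", "trends", "cpg", "methylation", "mirna", "qscore")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "results/pipeline",
    "stages": {name: True for name in STAGE_NAMES},
    "simulate": {
        "n_genes": 1000,
        "n_per_group": 10,
        "n_trend_up": 25,
        "n_trend_down": 25,
        "step_effect": 1.5,
        "noise_sd": 1.0,
        "n_reads": 200,
        "n_meth_samples": 3,
        "read_sub_rate": 0.005,
        "read_indel_rate": 0.005,
        "conversion_efficiency": 0.995,
        "mirna_shift": -3.0,
        "ct_noise_sd": 0.25,
        "qscore_noise_sd": 8.0,
    },
    "trends": {"tau_min": 0.5, "alpha": 0.05, "logfc_min": 1.0, "welch": False},
    "cpg": {"window": 100, "shift": 1, "min_len": 200, "min_gc": 50.0,
            "min_oe": 0.6},
    "align": {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0,
              "gap_extend": -1.0, "min_fraction": 0.80},
    "methylation": {"alpha": 0.05, "distance": "euclidean",
                    "linkage": "average", "k": 2},
    "mirna": {"alpha": 0.05},
    "inputs": {
        "expression_matrix": None,
        "expression_annotation": None,
        "template_fasta": None,
        "reads_dir": None,
        "promoter_fasta": None,
        "ct_plates": None,
        "prediction_table": None,
        "qscore_table": None,
    },
}

#: inputs each stage needs when not simulated
_REQUIRED_INPUTS = {
    "trends": ["expression_matrix", "expression_annotation"],
    "cpg": ["promoter_fasta"],
    "methylation": ["template_fasta", "reads_dir"],
    "mirna": ["ct_plates"],
    "qscore": ["qscore_table"],
}


class PipelineConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (defaults merged in)."""

    settings: dict = field(default_factory=lambda: deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.settings[key]

    @property
    def seed(self) -> int:
        return self.settings["seed"]

    @property
    def outdir(self) -> Path:
        return Path(self.settings["outdir"])


def _merge(defaults: dict, user: dict, prefix: str, errors: list[str]) -> dict:
    out = deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            errors.append(f"unknown key: {prefix}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, f"{prefix}{key}.", errors)
        else:
            out[key] = val
    return out


def _validate_settings(cfg: dict, errors: list[str]) -> None:
    t = cfg["trends"]
    if not t["tau_min"] > 0:
        errors.append("trends.tau_min must be positive")
    for section, key in (("trends", "alpha"), ("methylation", "alpha"),
                         ("mirna", "alpha")):
        if not 0 < cfg[section][key] < 1:
            errors.append(f"{section}.{key} must lie in (0, 1)")
    if not t["logfc_min"] > 0:
        errors.append("trends.logfc_min must be positive")
    a = cfg["align"]
    if not 0 < a["min_fraction"] <= 1:
        errors.append("align.min_fraction must lie in (0, 1]")
    if a["match"] <= 0:
        errors.append("align.match must be positive")
    c = cfg["cpg"]
    if c["window"] < 2 or c["shift"] < 1 or c["min_len"] < 1:
        errors.append("cpg window/shift/min_len out of range")
    if not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    sim_on = cfg["stages"].get("simulate", False)
    if not sim_on:
        for stage, inputs in _REQUIRED_INPUTS.items():
            if not cfg["stages"].get(stage, False):
                continue
            for name in inputs:
                path = cfg["inputs"].get(name)
                if path is None:
                    errors.append(f"stage {stage}: missing input {name}")
                elif not Path(path).exists():
                    errors.append(f"stage {stage}: input not found: {path}")


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration, reporting all errors at once."""
    errors: list[str] = []
    try:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as e:
        raise PipelineConfigError([f"cannot read config: {e}"]) from e
    if not isinstance(user, dict):
        raise PipelineConfigError(["config must be a YAML mapping"])
    cfg = _merge(DEFAULTS, user, "", errors)
    _validate_settings(cfg, errors)
    if errors:
        raise PipelineConfigError(errors)
    return PipelineConfig(cfg)


def _stage_seed(seed: int, name: str) -> int:
    """Named per-stage substream seed derived from the global seed."""
    idx = {"expression": 1, "reads": 2, "mirna": 3, "qscore": 4}[name]
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


# group-level true methylation per CpG site for the simulated methylation
# study: one hypermethylation assay (rising along the sequence, the
# PRIMA1-like pattern) and one flat control assay
_SIM_METH_TRUTH = {
    "sim_hyper": {"NAT": [0.05, 0.10, 0.10], "AD": [0.35, 0.40, 0.35],
                  "CRC": [0.70, 0.80, 0.75]},
    "sim_flat": {"NAT": [0.50, 0.45, 0.50], "AD": [0.50, 0.45, 0.50],
                 "CRC": [0.50, 0.45, 0.50]},
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the summary dict.

    Writes per-stage tables under ``outdir``, a machine-readable
    ``summary.json``, and ``run_log.txt`` recording version, parameters and
    seed.  Identical configuration and seed give byte-identical bundles.
    """
    cfg = config.settings
    stages = cfg["stages"]
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    simulate = stages.get("simulate", False)
    summary: dict = {"seed": cfg["seed"], "version": __version__, "stages_run": []}
    sim = cfg["simulate"]

    gene_set: set[str] = set()

    if stages.get("trends", False):
        if simulate:
            matrix, truth = gen_staged_expression(
                n_genes=sim["n_genes"], n_per_group=sim["n_per_group"],
                n_trend_up=sim["n_trend_up"], n_trend_down=sim["n_trend_down"],
                step_effect=sim["step_effect"], noise_sd=sim["noise_sd"],
                seed=_stage_seed(cfg["seed"], "expression"),
            )
            io.write_expression(matrix, outdir / "expression_matrix.tsv",
                                outdir / "expression_samples.tsv")
            truth.to_json(outdir / "expression_truth.json")
            planted = set(truth.trend_genes)
        else:
            matrix = io.read_expression(cfg["inputs"]["expression_matrix"],
                                        cfg["inputs"]["expression_annotation"])
            planted = None
        t = cfg["trends"]
        result = select_markers(trend_table(matrix, welch=t["welch"]),
                                tau_min=t["tau_min"], alpha=t["alpha"],
                                logfc_min=t["logfc_min"])
        result["venn"] = venn_categorize(result, alpha=t["alpha"])
        result.to_csv(outdir / "trend_results.tsv", sep="\t",
                      float_format="%.6g")
        selected = result.index[result["selected"]]
        gene_set = set(selected)
        summary["trends"] = {
            "n_genes": int(len(result)),
            "n_selected": int(len(selected)),
            "selected": sorted(selected),
            "venn_counts": {k: int(v) for k, v in
                            result["venn"].value_counts().sort_index().items()},
        }
        if planted is not None:
            tp = len(gene_set & planted)
            summary["trends"]["planted_recovery"] = {
                "sensitivity": round(tp / len(planted), 4) if planted else None,
                "fdr": round((len(gene_set) - tp) / max(len(gene_set), 1), 4),
            }
        summary["stages_run"].append("trends")

    if stages.get("cpg", False):
        if simulate:
            # synthetic promoter: a CpG-island core flanked by AT-rich arms
            promoter = ("ATTAGTTAGGTTAGGATTTA" * 15 + "GCGC" * 75
                        + "TTAGGATTAGTTAGGTTTAG" * 15)
            name = "sim_promoter"
        else:
            recs = io.read_fasta(cfg["inputs"]["promoter_fasta"])
            name, promoter = recs[0]
        c = cfg["cpg"]
        islands = predict_islands(promoter, window=c["window"], shift=c["shift"],
                                  min_len=c["min_len"], min_gc=c["min_gc"],
                                  min_oe=c["min_oe"])
        io.write_islands_bed(name, islands, outdir / "cpg_islands.bed")
        summary["cpg"] = {
            "sequence": name,
            "n_islands": len(islands),
            "islands": [[i.start, i.end] for i in islands],
        }
        summary["stages_run"].append("cpg")

    if stages.get("methylation", False):
        scoring = ScoringScheme(cfg["align"]["match"], cfg["align"]["mismatch"],
                                cfg["align"]["gap_open"],
                                cfg["align"]["gap_extend"])
        min_frac = cfg["align"]["min_fraction"]
        per_sample: dict[str, pd.DataFrame] = {}
        groups = {}
        aln_rows = []
        if simulate:
            base_seed = _stage_seed(cfg["seed"], "reads")
            k = 0
            for assay, by_group in _SIM_METH_TRUTH.items():
                template = default_template(assay)
                for group, probs in by_group.items():
                    for s in range(sim["n_meth_samples"]):
                        sample = f"{group}{s + 1:02d}"
                        groups[sample] = group
                        k += 1
                        reads, _ = gen_bisulfite_reads(
                            template, probs, n_reads=sim["n_reads"],
                            conversion_efficiency=sim["conversion_efficiency"],
                            sub_rate=sim["read_sub_rate"],
                            indel_rate=sim["read_indel_rate"],
                            seed=(base_seed + k) % (2**31),
                        )
                        alns = [align_read(seq, template, scoring, read_id=rid)
                                for rid, seq in reads]
                        passing = filter_reads(alns, min_frac)
                        aln_rows.extend(alns)
                        table = call_cpg_methylation(passing, template)
                        per_sample.setdefault(sample, [])
                        per_sample[sample].append(table)
            per_sample = {s: pd.concat(ts) for s, ts in per_sample.items()}
            groups = pd.Series(groups)
        else:
            template = io.read_template(cfg["inputs"]["template_fasta"])
            reads_dir = Path(cfg["inputs"]["reads_dir"])
            annot = pd.read_csv(reads_dir / "samples.tsv", sep="\t", index_col=0)
            groups = annot["group"]
            for sample in annot.index:
                reads = io.read_fasta(reads_dir / annot.loc[sample, "reads"])
                alns = [align_read(seq, template, scoring, read_id=rid)
                        for rid, seq in reads]
                passing = filter_reads(alns, min_frac)
                aln_rows.extend(alns)
                per_sample[sample] = call_cpg_methylation(passing, template)
        io.write_alignment_report(aln_rows, outdir / "alignments.tsv")
        mm = build_methylation_matrix(per_sample, groups)
        mm.values.to_csv(outdir / "methylation_matrix.tsv", sep="\t",
                         float_format="%.4f")
        m = cfg["methylation"]
        comparison = compare_methylation_groups(mm, alpha=m["alpha"])
        comparison.to_csv(outdir / "methylation_comparison.tsv", sep="\t",
                          float_format="%.6g")
        n_pass = sum(1 for a in aln_rows if a.passed)
        summary["methylation"] = {
            "n_reads": len(aln_rows),
            "n_passing": n_pass,
            "pass_rate": round(n_pass / max(len(aln_rows), 1), 4),
            "classes": {
                assay: {"AD": comparison.loc[assay, "class_AD"],
                        "CRC": comparison.loc[assay, "class_CRC"]}
                for assay in comparison.index
            },
        }
        if mm.values.shape[0] >= 2:
            clustering = cluster_markers(mm, distance=m["distance"],
                                         linkage=m["linkage"], k=m["k"])
            summary["methylation"]["cluster_row_order"] = clustering["row_order"]
            if "row_clusters" in clustering:
                summary["methylation"]["row_clusters"] = clustering["row_clusters"]
        summary["stages_run"].append("methylation")

    if stages.get("mirna", False):
        if simulate:
            shift = sim["mirna_shift"]
            planted_shifts = {"miR-21": {"AD": shift, "CRC": shift},
                              "miR-181c": {"CRC": shift}}
            plates, mtruth = gen_ct_plates(
                planted_shifts=planted_shifts, noise_sd=sim["ct_noise_sd"],
                seed=_stage_seed(cfg["seed"], "mirna"),
            )
            io.write_ct_plates(plates, outdir / "ct_plates.tsv")
            mtruth.to_json(outdir / "mirna_truth.json")
            mirna_groups = pd.Series(mtruth.group_assignments)
            prediction = pd.DataFrame(
                [{"mirna": m_, "gene": g} for m_, genes in
                 {"miR-21": sorted(gene_set)[:5] or ["gene_00000"],
                  "miR-181c": sorted(gene_set)[:2] or ["gene_00000"]}.items()
                 for g in genes]
            )
        else:
            plates = io.read_ct_plates(cfg["inputs"]["ct_plates"])
            sample_ids = sorted(set(
                plates.wells.loc[~plates.wells["is_calibrator"], "sample"]))
            mirna_groups = pd.Series(
                {s: s.rstrip("0123456789_") for s in sample_ids})
            prediction = (io.read_prediction_table(cfg["inputs"]["prediction_table"])
                          if cfg["inputs"]["prediction_table"] else
                          pd.DataFrame(columns=["mirna", "gene"]))
        normalized, flagged = normalize_panel(plates)
        normalized.to_csv(outdir / "mirna_normalized.tsv", sep="\t",
                          float_format="%.4f")
        comparison = compare_mirna_groups(normalized, mirna_groups,
                                          alpha=cfg["mirna"]["alpha"])
        comparison.to_csv(outdir / "mirna_comparison.tsv", sep="\t",
                          float_format="%.6g")
        differential = [m_ for m_ in comparison.index
                        if comparison.loc[m_, "upregulated_in"]]
        summary["mirna"] = {
            "n_mirnas": int(len(normalized)),
            "excluded_samples": flagged,
            "upregulated": sorted(differential),
        }
        if len(prediction) and gene_set:
            ranking = rank_mirnas_by_targets(differential, prediction, gene_set)
            ranking.to_csv(outdir / "mirna_target_ranking.tsv", sep="\t")
            summary["mirna"]["target_ranking"] = [
                {"mirna": m_, "n_targets": int(r["n_targets"])}
                for m_, r in ranking.iterrows()
            ]
        summary["stages_run"].append("mirna")

    if stages.get("qscore", False):
        if simulate:
            cores = gen_qscore_cores(noise_sd=sim["qscore_noise_sd"],
                                     seed=_stage_seed(cfg["seed"], "qscore"))
            cores.to_csv(outdir / "qscore_cores.tsv", sep="\t", index=False,
                         float_format="%.4f")
        else:
            cores = pd.read_csv(cfg["inputs"]["qscore_table"], sep="\t")
        qs = summarize_qscores(cores)
        summary["qscore"] = qs
        summary["stages_run"].append("qscore")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"amplimeth {__version__}\nseed: {cfg['seed']}\n")
        fh.write("parameters:\n")
        fh.write(yaml.safe_dump({k: cfg[k] for k in
                                 ("stages", "trends", "cpg", "align",
                                  "methylation", "mirna", "simulate")},
                                sort_keys=True))
    return summary
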