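#!/usr/bin/env python
"""Normalize the simulated miRNA Ct panel and rank differential miRNAs by
predicted targets among the selected trend genes.

Applies the normalization chain (invert to 45 − Ct, interplate calibration,
miR-423-5p reference normalization), tests lesion groups against NAT, and
intersects upregulated miRNAs with the marker set from 02_select_trends.py
through a small prediction table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from amplimeth import io
from amplimeth.mirna import (
    compare_mirna_groups,
    normalize_panel,
    rank_mirnas_by_targets,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--inputs", type=Path,
                        default=ROOT / "results" / "synthetic")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    plates = io.read_ct_plates(args.inputs / "ct_plates.tsv")
    normalized, flagged = normalize_panel(plates)
    normalized.to_csv(args.out / "mirna_normalized.tsv", sep="\t",
                      float_format="%.4f")
    if flagged:
        print(f"samples excluded (missing reference): {flagged}")

    truth = json.loads((args.inputs / "mirna_truth.json").read_text())
    groups = pd.Series(truth["group_assignments"])
    comparison = compare_mirna_groups(normalized, groups, alpha=0.01)
    comparison.to_csv(args.out / "mirna_comparison.tsv", sep="\t",
                      float_format="%.6g")
    up = [m for m in comparison.index if comparison.loc[m, "upregulated_in"]]
    print(f"upregulated (p < 0.01 vs NAT): {up}")
    print(f"planted: {sorted(truth['differential_mirnas'])}")

    trend_path = args.out / "trend_results.tsv"
    if trend_path.exists():
        trends = pd.read_csv(trend_path, sep="\t", index_col=0)
        gene_set = set(trends.index[trends["selected"]])
        prediction = pd.DataFrame(
            [{"mirna": m, "gene": g}
             for m, genes in {"miR-21": sorted(gene_set)[:5],
                              "miR-181c": sorted(gene_set)[:2]}.items()
             for g in genes])
        ranking = rank_mirnas_by_targets(up, prediction, gene_set)
        ranking.to_csv(args.out / "mirna_target_ranking.tsv", sep="\t")
        print("target ranking:")
        print(ranking.to_string())


if __name__ == "__main__":
    main()
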