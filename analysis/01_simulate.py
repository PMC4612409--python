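#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes, under results/synthetic/: a stage-labelled log2 expression matrix
(1000 genes, 10 samples per stage, 25 up- and 25 down-trending genes planted
at 1.5 log2 units per stage), bisulfite amplicon reads for two assays (one
hypermethylating along the sequence, one flat) across 3 samples per stage,
a two-plate miRNA Ct panel with a planted −3 Ct miR-21 shift, and a TMA
Q-score core table with decreasing group means.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from amplimeth import io
from amplimeth.synthetic import (
    default_template,
    gen_bisulfite_reads,
    gen_ct_plates,
    gen_qscore_cores,
    gen_staged_expression,
)

ROOT = Path(__file__).resolve().parents[1]

# group-level true methylation per CpG site for the two simulated assays
METH_TRUTH = {
    "sim_hyper": {"NAT": [0.05, 0.10, 0.10], "AD": [0.35, 0.40, 0.35],
                  "CRC": [0.70, 0.80, 0.75]},
    "sim_flat": {"NAT": [0.50, 0.45, 0.50], "AD": [0.50, 0.45, 0.50],
                 "CRC": [0.50, 0.45, 0.50]},
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "synthetic")
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    matrix, truth = gen_staged_expression(seed=args.seed)
    io.write_expression(matrix, out / "expression_matrix.tsv",
                        out / "expression_samples.tsv")
    truth.to_json(out / "expression_truth.json")
    print(f"expression: {matrix.values.shape[0]} genes x "
          f"{matrix.values.shape[1]} samples, "
          f"{len(truth.trend_genes)} planted trend genes")

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    meth_truth = {}
    rows = []
    k = 0
    for assay, by_group in METH_TRUTH.items():
        template = default_template(assay)
        io.write_fasta([(assay, template.seq)], out / f"{assay}.fasta")
        io.write_cpg_bed(template, out / f"{assay}.cpg.bed")
        for group, probs in by_group.items():
            for s in range(3):
                sample = f"{group}{s + 1:02d}"
                k += 1
                reads, rtruth = gen_bisulfite_reads(
                    template, probs, n_reads=200,
                    conversion_efficiency=0.995, sub_rate=0.005,
                    indel_rate=0.005, seed=args.seed * 1000 + k)
                fname = f"{assay}_{sample}.fasta"
                io.write_fasta(reads, reads_dir / fname)
                meth_truth[f"{assay}/{sample}"] = rtruth.cpg_methylated_draws
                rows.append({"sample": sample, "assay": assay,
                             "group": group, "reads": fname})
    pd.DataFrame(rows).to_csv(out / "reads_manifest.tsv", sep="\t",
                              index=False)
    with open(out / "methylation_truth.json", "w") as fh:
        json.dump(meth_truth, fh, indent=1, sort_keys=True)
    print(f"reads: {k} sample/assay read sets of 200 reads each")

    plates, mtruth = gen_ct_plates(
        planted_shifts={"miR-21": {"AD": -3.0, "CRC": -3.0},
                        "miR-181c": {"CRC": -3.0}},
        seed=args.seed + 1)
    io.write_ct_plates(plates, out / "ct_plates.tsv")
    mtruth.to_json(out / "mirna_truth.json")
    print(f"miRNA panel: {plates.wells['mirna'].nunique() - 1} miRNAs, "
          f"planted shifts in {sorted(mtruth.differential_mirnas)}")

    cores = gen_qscore_cores(seed=args.seed + 2)
    cores.to_csv(out / "qscore_cores.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print(f"IHC: {len(cores)} TMA cores written")


if __name__ == "__main__":
    main()
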