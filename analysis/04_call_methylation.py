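#!/usr/bin/env python
"""Align bisulfite reads, call per-CpG methylation, compare groups, cluster.

For every sample/assay read set from 01_simulate.py: Smith-Waterman-Gotoh
alignment against the converted template references, the 80%-of-maximum
score filter, per-CpG C/T counting, assay-level summaries on the percent
scale, pooled t-test group comparisons with hyper/hypomethylation classes,
and hierarchical clustering of the assay × sample matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from amplimeth import io
from amplimeth.align import align_read, filter_reads
from amplimeth.methylation import (
    build_methylation_matrix,
    call_cpg_methylation,
    cluster_markers,
    compare_methylation_groups,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--inputs", type=Path,
                        default=ROOT / "results" / "synthetic")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(args.inputs / "reads_manifest.tsv", sep="\t")
    templates = {
        assay: io.read_template(args.inputs / f"{assay}.fasta",
                                args.inputs / f"{assay}.cpg.bed")
        for assay in manifest["assay"].unique()
    }
    per_sample: dict[str, list] = {}
    groups = {}
    all_alns = []
    for _, row in manifest.iterrows():
        template = templates[row["assay"]]
        reads = io.read_fasta(args.inputs / "reads" / row["reads"])
        alns = [align_read(seq, template, read_id=rid) for rid, seq in reads]
        passing = filter_reads(alns)
        all_alns.extend(alns)
        table = call_cpg_methylation(passing, template)
        per_sample.setdefault(row["sample"], []).append(table)
        groups[row["sample"]] = row["group"]
    n_pass = sum(a.passed for a in all_alns)
    print(f"{n_pass}/{len(all_alns)} reads pass the 80% score filter "
          f"({100 * n_pass / len(all_alns):.1f}%)")
    io.write_alignment_report(all_alns, args.out / "alignments.tsv")

    merged = {s: pd.concat(ts) for s, ts in per_sample.items()}
    mm = build_methylation_matrix(merged, pd.Series(groups))
    mm.values.to_csv(args.out / "methylation_matrix.tsv", sep="\t",
                     float_format="%.4f")
    comparison = compare_methylation_groups(mm)
    comparison.to_csv(args.out / "methylation_comparison.tsv", sep="\t",
                      float_format="%.6g")
    for assay in comparison.index:
        print(f"{assay}: NAT {comparison.loc[assay, 'mean_NAT']:.1f}% | "
              f"AD {comparison.loc[assay, 'mean_AD']:.1f}% "
              f"({comparison.loc[assay, 'class_AD']}) | "
              f"CRC {comparison.loc[assay, 'mean_CRC']:.1f}% "
              f"({comparison.loc[assay, 'class_CRC']})")

    clustering = cluster_markers(mm, k=2)
    print("row clusters at k=2:", clustering["row_clusters"])


if __name__ == "__main__":
    main()
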