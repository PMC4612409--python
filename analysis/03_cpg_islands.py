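#!/usr/bin/env python
"""Predict CpG islands in the simulated amplicon/promoter sequences.

Runs the sliding-window observed/expected CpG scan (window 100, GC% > 50,
Obs/Exp > 0.6, merged spans ≥ 200 nt) over every template FASTA written by
01_simulate.py plus a constructed island-bearing promoter, writing BED calls
to results/cpg_islands.bed.
"""

import argparse
from pathlib import Path

from amplimeth import io
from amplimeth.cpg import list_cpg_sites, predict_islands

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--inputs", type=Path,
                        default=ROOT / "results" / "synthetic")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sequences = []
    for fasta in sorted(args.inputs.glob("sim_*.fasta")):
        sequences.extend(io.read_fasta(fasta))
    # a promoter-like construction: AT-rich arms around a CpG-island core
    promoter = ("ATTAGTTAGGTTAGGATTTA" * 15 + "GCGC" * 75
                + "TTAGGATTAGTTAGGTTTAG" * 15)
    sequences.append(("sim_promoter", promoter))

    with open(args.out / "cpg_islands.bed", "w") as fh:
        for name, seq in sequences:
            islands = predict_islands(seq)
            n_sites = len(list_cpg_sites(seq))
            print(f"{name}: {len(seq)} nt, {n_sites} CpG sites, "
                  f"{len(islands)} island(s) "
                  f"{[(i.start, i.end) for i in islands]}")
            for k, isl in enumerate(islands):
                fh.write(f"{name}\t{isl.start}\t{isl.end}\tisland_{k + 1}\t"
                         f"{isl.gc_percent:.2f}\t{isl.obs_exp:.3f}\n")


if __name__ == "__main__":
    main()
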