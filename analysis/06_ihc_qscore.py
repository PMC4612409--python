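#!/usr/bin/env python
"""Summarize the simulated TMA Quick-scores per stage group.

Reads the core table from 01_simulate.py, computes per-group Q-score
mean ± SD and reports whether protein expression changes monotonically
along the NAT → adenoma → carcinoma sequence.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from amplimeth.ihc import summarize_qscores

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--inputs", type=Path,
                        default=ROOT / "results" / "synthetic")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cores = pd.read_csv(args.inputs / "qscore_cores.tsv", sep="\t")
    summary = summarize_qscores(cores)
    with open(args.out / "qscore_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    for g, stats in summary["groups"].items():
        print(f"{g}: Q-score {stats['mean']:.1f} ± {stats['sd']:.1f} "
              f"(n={stats['n']})")
    trend = ("decreasing" if summary["decreasing"]
             else "increasing" if summary["increasing"] else "no monotone")
    print(f"trend along NAT→AD→CRC: {trend}")


if __name__ == "__main__":
    main()
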