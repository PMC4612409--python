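"""Semiquantitative immunohistochemistry Quick-score (Q-score) summaries.

Each tissue-microarray core is scored as the percentage of positive cells
(0–100) multiplied by the staining intensity (0 none, 1 weak, 2 moderate,
3 strong), giving a Q-score in [0, 300].  Group summaries report mean ± SD
per stage and whether the means change monotonically along the
NAT → adenoma → carcinoma order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QScoreRecord", "qscore", "summarize_qscores", "GROUP_ORDER"]

GROUP_ORDER = ("NAT", "AD", "CRC")


def qscore(percent_positive: float, intensity: int) -> float:
    """Q-score = percent positive cells × intensity, in [0, 300]."""
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent positive cells must lie in [0, 100]")
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be one of 0, 1, 2, 3")
    return float(percent_positive) * intensity


@dataclass(frozen=True)
class QScoreRecord:
    core_id: str
    group: str  # NAT | AD | CRC
    percent_positive: float
    intensity: int

    def __post_init__(self) -> None:
        if self.group not in GROUP_ORDER:
            raise ValueError(f"unknown group {self.group!r}")
        qscore(self.percent_positive, self.intensity)  # validates ranges

    @property
    def qscore(self) -> float:
        return qscore(self.percent_positive, self.intensity)


def summarize_qscores(records: list[QScoreRecord] | pd.DataFrame) -> dict:
    """Per-group Q-score mean ± SD and monotone-trend flags along the stages.

    Accepts records or a DataFrame with columns core_id, group,
    percent_positive, intensity.  Groups without records are excluded with a
    warning and break any trend claim.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        df["qscore"] = [
            qscore(p, int(i))
            for p, i in zip(df["percent_positive"], df["intensity"])
        ]
    else:
        df = pd.DataFrame(
            [
                {"core_id": r.core_id, "group": r.group, "qscore": r.qscore}
                for r in records
            ]
        )
    present = [g for g in GROUP_ORDER if (df["group"] == g).any()]
    absent = [g for g in GROUP_ORDER if g not in present]
    if absent:
        warnings.warn(f"groups without cores excluded: {absent}")
    summary = {
        g: {
            "n": int((df["group"] == g).sum()),
            "mean": float(df.loc[df["group"] == g, "qscore"].mean()),
            "sd": float(df.loc[df["group"] == g, "qscore"].std(ddof=1))
            if (df["group"] == g).sum() > 1 else float("nan"),
        }
        for g in present
    }
    means = [summary[g]["mean"] for g in present]
    complete = len(present) == len(GROUP_ORDER)
    return {
        "groups": summary,
        "decreasing": complete and all(a > b for a, b in zip(means, means[1:])),
        "increasing": complete and all(a < b for a, b in zip(means, means[1:])),
    }
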