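"""miRNA qPCR Ct normalization and target-based ranking.

Raw Ct values are first inverted to an expression-like scale (max cycle − Ct,
max cycle 45, so lower Ct = higher abundance maps to a larger number), then
plate-to-plate offsets are removed using the interplate calibrator wells
(each plate's calibrator deviation from the across-plate calibrator mean is
subtracted from every well on that plate), and finally each sample is
normalized to the reference miRNA miR-423-5p by subtracting the sample's
reference value.  Undetected wells stay missing throughout; they are never
imputed at the maximum cycle.

Differential miRNAs can be related to a gene set of interest through a
user-supplied target-prediction table (miRNA → gene), ranking miRNAs by how
many genes of the set they are predicted to target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtPlateSet",
    "invert_ct",
    "calibrate_plates",
    "normalize_reference",
    "normalize_panel",
    "compare_mirna_groups",
    "rank_mirnas_by_targets",
    "REFERENCE_MIRNA",
    "CALIBRATOR_ID",
    "MAX_CYCLE",
]

REFERENCE_MIRNA = "miR-423-5p"
CALIBRATOR_ID = "UniSp3_IPC"
MAX_CYCLE = 45.0


@dataclass
class CtPlateSet:
    """Long-format raw Ct measurements across one or more plates.

    ``wells`` columns: mirna, sample, plate, ct, is_calibrator.  Calibrator
    rows carry one interplate-calibrator Ct per plate (sample = "calibrator").
    """

    wells: pd.DataFrame
    reference: str = REFERENCE_MIRNA
    max_cycle: float = MAX_CYCLE

    def __post_init__(self) -> None:
        need = {"mirna", "sample", "plate", "ct", "is_calibrator"}
        if not need <= set(self.wells.columns):
            raise ValueError(f"plate table needs columns {sorted(need)}")
        ct = self.wells["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > self.max_cycle))
        if bad.any():
            raise ValueError(f"Ct values outside (0, {self.max_cycle}]")
        measured = set(self.wells.loc[~self.wells["is_calibrator"], "mirna"])
        if self.reference not in measured:
            raise ValueError(f"reference miRNA {self.reference!r} not measured")


def invert_ct(raw_ct, max_cycle: float = MAX_CYCLE):
    """Expression-scale value max_cycle − Ct; missing stays missing."""
    arr = np.asarray(raw_ct, dtype=float)
    if np.any(arr[~np.isnan(arr)] > max_cycle):
        raise ValueError(f"Ct above the maximal cycle number {max_cycle}")
    out = max_cycle - arr
    return float(out) if np.isscalar(raw_ct) or arr.ndim == 0 else out


def calibrate_plates(plates: CtPlateSet) -> pd.DataFrame:
    """Interplate calibration on the inverted scale.

    Subtracts each plate's calibrator deviation from the across-plate
    calibrator mean from all sample wells on that plate.  Returns the well
    table with an ``inverted`` column of calibrated values.
    """
    wells = plates.wells.copy()
    wells["inverted"] = invert_ct(wells["ct"].to_numpy(), plates.max_cycle)
    cal = wells[wells["is_calibrator"]]
    cal_by_plate = cal.groupby("plate")["inverted"].mean()
    missing = set(wells["plate"]) - set(cal_by_plate.dropna().index)
    if missing:
        raise ValueError(f"plates without calibrator: {sorted(missing)}")
    deviation = cal_by_plate - cal_by_plate.mean()
    out = wells[~wells["is_calibrator"]].copy()
    out["inverted"] = out["inverted"] - out["plate"].map(deviation)
    return out


def normalize_reference(
    values: pd.DataFrame, reference: str = REFERENCE_MIRNA
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample reference normalization of an inverted miRNA × sample matrix.

    Subtracts each sample's reference-miRNA value from every miRNA of that
    sample.  Samples missing the reference are dropped and reported in the
    second return value.
    """
    if reference not in values.index:
        raise ValueError(f"reference miRNA {reference!r} absent from matrix")
    ref = values.loc[reference]
    flagged = [s for s in values.columns if pd.isna(ref[s])]
    if flagged:
        warnings.warn(f"samples without reference measurement: {flagged}")
    keep = [s for s in values.columns if s not in flagged]
    return values[keep].sub(ref[keep], axis=1), flagged


def normalize_panel(plates: CtPlateSet) -> tuple[pd.DataFrame, list[str]]:
    """Full normalization: invert → interplate calibration → reference.

    Returns the normalized miRNA × sample matrix (reference row removed) and
    the list of samples excluded for a missing reference value.
    """
    calibrated = calibrate_plates(plates)
    wide = calibrated.pivot_table(
        index="mirna", columns="sample", values="inverted", aggfunc="mean"
    )
    normalized, flagged = normalize_reference(wide, plates.reference)
    return normalized.drop(index=plates.reference), flagged


def compare_mirna_groups(
    normalized: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled-variance t-tests of normalized values, lesion groups vs NAT."""
    comparisons = {"N_vs_AD": ("NAT", "AD"), "N_vs_CRC": ("NAT", "CRC")}
    rows = []
    for mirna in normalized.index:
        series = normalized.loc[mirna]
        row: dict = {"mirna": mirna}
        for g in ("NAT", "AD", "CRC"):
            vals = series[groups[series.index] == g].dropna()
            row[f"mean_{g}"] = vals.mean() if len(vals) else np.nan
        for name, (ga, gb) in comparisons.items():
            a = series[groups[series.index] == ga].dropna()
            b = series[groups[series.index] == gb].dropna()
            if len(a) < 2 or len(b) < 2:
                row[f"p_{name}"] = np.nan
                continue
            with np.errstate(divide="ignore", invalid="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(a, b, equal_var=True)
            row[f"p_{name}"] = 1.0 if np.isnan(res.statistic) else float(res.pvalue)
        up = [
            g for g, name in (("AD", "N_vs_AD"), ("CRC", "N_vs_CRC"))
            if not np.isnan(row[f"p_{name}"])
            and row[f"p_{name}"] < alpha
            and row[f"mean_{g}"] > row["mean_NAT"]
        ]
        row["upregulated_in"] = ",".join(up)
        rows.append(row)
    return pd.DataFrame(rows).set_index("mirna")


def rank_mirnas_by_targets(
    mirnas: list[str],
    prediction_table: pd.DataFrame,
    gene_set: set[str],
) -> pd.DataFrame:
    """Rank miRNAs by how many genes of ``gene_set`` they target.

    ``prediction_table`` needs columns ``mirna`` and ``gene``.  Ordering is
    deterministic: target count descending, then miRNA id ascending.
    """
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    if len(prediction_table) == 0:
        warnings.warn("empty prediction table: no targets to rank")
        return pd.DataFrame(columns=["n_targets", "targets"])
    need = {"mirna", "gene"}
    if not need <= set(prediction_table.columns):
        raise ValueError(f"prediction table needs columns {sorted(need)}")
    rows = []
    targets = prediction_table.groupby("mirna")["gene"].agg(set)
    for m in mirnas:
        hit = sorted(targets.get(m, set()) & gene_set)
        rows.append({"mirna": m, "n_targets": len(hit), "targets": ",".join(hit)})
    df = pd.DataFrame(rows)
    df = df.sort_values(["n_targets", "mirna"], ascending=[False, True],
                        kind="mergesort")
    return df.set_index("mirna")
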