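"""Trend-based marker selection along the normal → adenoma → carcinoma sequence.

Genes whose expression changes gradually along the ordered disease stages are
scored with the tie-corrected Kendall rank correlation (tau-b) of expression
against the ordinal stage code, tested pairwise between stage groups with a
pooled-variance Student t-test, and controlled for multiplicity with the
Benjamini-Hochberg step-up procedure applied across genes within each
comparison.  A gene is called a marker when it shows a strong monotone trend
(|tau| above a threshold) together with a significant and large
(|difference of group mean log2 intensities| above a threshold) change in at
least one normal-vs-lesion comparison.

The same machinery handles the two-condition demethylation re-expression
screen (control vs 5-Aza-treated cell lines) as a degenerate two-stage design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "TauResult",
    "kendall_tau_trend",
    "pairwise_group_tests",
    "bh_adjust",
    "log_fold_change",
    "trend_table",
    "select_markers",
    "venn_categorize",
    "aza_reexpression",
    "STAGE_CODES",
    "COMPARISONS",
]

#: canonical ordinal codes for the adenoma-carcinoma sequence (and aliases)
STAGE_CODES: dict[str, int] = {
    "normal": 0, "NAT": 0, "N": 0,
    "adenoma": 1, "AD": 1,
    "CRC": 2, "carcinoma": 2, "tumour": 2, "tumor": 2,
    # two-condition demethylation screen
    "control": 0, "treated": 1,
}

#: the three pairwise stage comparisons, as (code A, code B) -> column suffix
COMPARISONS: dict[str, tuple[int, int]] = {
    "N_vs_AD": (0, 1),
    "N_vs_CRC": (0, 2),
    "AD_vs_CRC": (1, 2),
}

VALID_CONTEXTS = {"biopsy", "LCM_epithelium", "LCM_stroma", "cell_line"}


@dataclass
class ExpressionMatrix:
    """Probes/genes × samples log2 intensity matrix with ordered stage labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probe id with one column per sample.
    samples
        Sample annotation indexed by sample id with columns ``stage``
        (a key of :data:`STAGE_CODES`) and optionally ``context``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.samples.index):
            missing = set(self.values.columns) - set(self.samples.index)
            raise ValueError(f"samples lack annotation: {sorted(missing)}")
        if "stage" not in self.samples.columns:
            raise ValueError("sample annotation needs a 'stage' column")
        unknown = set(self.samples["stage"]) - set(STAGE_CODES)
        if unknown:
            raise ValueError(f"unknown stage labels: {sorted(unknown)}")
        if self.samples["stage"].isna().any():
            raise ValueError("missing stage labels")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")

    @property
    def stage_codes(self) -> pd.Series:
        """Ordinal stage code per sample, in the column order of ``values``."""
        return self.samples.loc[self.values.columns, "stage"].map(STAGE_CODES)

    def group_columns(self, code: int) -> list[str]:
        codes = self.stage_codes
        return [c for c in self.values.columns if codes[c] == code]


@dataclass
class TauResult:
    tau: float
    degenerate: bool = False


def kendall_tau_trend(values, stages) -> TauResult:
    """Tie-corrected Kendall tau-b of expression against ordinal stage codes.

    Constant expression vectors have no defined rank correlation; they return
    tau 0 with ``degenerate=True`` so callers can keep them out of selections
    without special-casing NaN.
    """
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages)
    if values.shape != stages.shape:
        raise ValueError("values and stages must have equal length")
    if len(np.unique(stages)) < 2:
        raise ValueError("trend undefined: a single stage is present")
    if np.all(values == values[0]):
        return TauResult(0.0, degenerate=True)
    tau = stats.kendalltau(values, stages, variant="b").statistic
    return TauResult(float(tau), degenerate=bool(np.isnan(tau)))


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t-test p-values, rows of a vs rows of b."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    # identical degenerate rows: t = 0/0 -> NaN; define p = 1 (no evidence)
    t = np.asarray(res.statistic, dtype=float)
    p[np.isnan(t)] = 1.0
    return p


def pairwise_group_tests(
    matrix: ExpressionMatrix, *, welch: bool = False
) -> pd.DataFrame:
    """Per-gene raw and BH-adjusted p-values for the three stage comparisons.

    Student's pooled-variance t-test by default (``welch=True`` switches to the
    unequal-variance form).  BH adjustment is applied across genes within each
    comparison.  A comparison whose groups do not both have ≥2 samples is
    reported as NaN; the other comparisons are unaffected.
    """
    codes = matrix.stage_codes
    out = pd.DataFrame(index=matrix.values.index)
    for name, (ca, cb) in COMPARISONS.items():
        cols_a = [c for c in matrix.values.columns if codes[c] == ca]
        cols_b = [c for c in matrix.values.columns if codes[c] == cb]
        if len(cols_a) < 2 or len(cols_b) < 2:
            out[f"p_{name}"] = np.nan
            out[f"q_{name}"] = np.nan
            continue
        a = matrix.values[cols_a].to_numpy(dtype=float)
        b = matrix.values[cols_b].to_numpy(dtype=float)
        if welch:
            with np.errstate(divide="ignore", invalid="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
            p = np.where(np.isnan(p), 1.0, p)
        else:
            p = _pooled_ttest(a, b)
        out[f"p_{name}"] = p
        out[f"q_{name}"] = bh_adjust(p)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    NaN entries stay NaN and do not count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def log_fold_change(
    matrix: ExpressionMatrix, comparison: str | tuple[int, int]
) -> pd.Series:
    """Difference of group mean log2 intensities, mean(B) − mean(A)."""
    ca, cb = COMPARISONS[comparison] if isinstance(comparison, str) else comparison
    cols_a = matrix.group_columns(ca)
    cols_b = matrix.group_columns(cb)
    if not cols_a or not cols_b:
        raise ValueError(f"comparison {comparison}: empty group")
    return matrix.values[cols_b].mean(axis=1) - matrix.values[cols_a].mean(axis=1)


def trend_table(matrix: ExpressionMatrix, *, welch: bool = False) -> pd.DataFrame:
    """Full per-gene trend result: tau, p/q and logFc per comparison.

    This is the table the marker-selection and Venn steps consume.
    """
    vals = matrix.values.to_numpy(dtype=float)
    codes = matrix.stage_codes.to_numpy()
    taus = np.empty(vals.shape[0])
    degen = np.zeros(vals.shape[0], dtype=bool)
    for i in range(vals.shape[0]):
        r = kendall_tau_trend(vals[i], codes)
        taus[i] = r.tau
        degen[i] = r.degenerate
    res = pd.DataFrame({"tau": taus, "tau_degenerate": degen},
                       index=matrix.values.index)
    res = res.join(pairwise_group_tests(matrix, welch=welch))
    present = sorted(set(codes))
    for name, (ca, cb) in COMPARISONS.items():
        if ca in present and cb in present:
            res[f"logfc_{name}"] = log_fold_change(matrix, name)
        else:
            res[f"logfc_{name}"] = np.nan
    return res


def select_markers(
    result: pd.DataFrame,
    tau_min: float = 0.5,
    alpha: float = 0.05,
    logfc_min: float = 1.0,
) -> pd.DataFrame:
    """Apply the marker rule to a :func:`trend_table` result.

    Selected iff |tau| ≥ ``tau_min`` and, in at least one normal-vs-lesion
    comparison, BH-adjusted p < ``alpha`` together with |logFc| > ``logfc_min``
    in that same comparison.  Direction is the sign of tau.
    """
    if tau_min <= 0 or alpha <= 0 or logfc_min <= 0:
        raise ValueError("thresholds must be positive")
    out = result.copy()
    trend_ok = (out["tau"].abs() >= tau_min) & ~out["tau_degenerate"]
    lesion_ok = pd.Series(False, index=out.index)
    for name in ("N_vs_AD", "N_vs_CRC"):
        hit = (out[f"q_{name}"] < alpha) & (out[f"logfc_{name}"].abs() > logfc_min)
        lesion_ok |= hit.fillna(False)
    out["selected"] = trend_ok & lesion_ok
    out["direction"] = np.where(out["tau"] > 0, "up", "down")
    out.loc[out["tau"] == 0, "direction"] = "none"
    return out


def venn_categorize(result: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Classify genes by which normal-vs-lesion comparison is significant.

    Categories mirror the two-set Venn diagram over the normal-vs-adenoma and
    normal-vs-carcinoma comparisons: ``both``, ``AD_only``, ``CRC_only``,
    ``neither``; ``not_evaluable`` when an adjusted p is missing.
    """
    q_ad = result["q_N_vs_AD"]
    q_crc = result["q_N_vs_CRC"]
    cat = pd.Series("neither", index=result.index, dtype=object)
    cat[(q_ad < alpha) & (q_crc < alpha)] = "both"
    cat[(q_ad < alpha) & ~(q_crc < alpha)] = "AD_only"
    cat[~(q_ad < alpha) & (q_crc < alpha)] = "CRC_only"
    cat[q_ad.isna() | q_crc.isna()] = "not_evaluable"
    return cat


def aza_reexpression(matrix: ExpressionMatrix, logfc_min: float = 1.0) -> pd.DataFrame:
    """Demethylation re-expression screen on a control/treated two-group design.

    logFc is mean(treated) − mean(control); a gene is flagged re-expressed when
    logFc exceeds ``logfc_min`` (upregulated after 5-Aza, consistent with
    methylation-silenced expression).
    """
    lfc = log_fold_change(matrix, (0, 1))
    return pd.DataFrame({
        "logfc_treated_vs_control": lfc,
        "reexpressed": lfc > logfc_min,
    })
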