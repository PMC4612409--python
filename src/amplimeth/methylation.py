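"""Per-CpG methylation calling, group comparison and marker clustering.

For each CpG column of an amplicon the bases of passing reads aligned to that
column are counted: C means methylated, T unmethylated (on the reverse
orientation the complementary G/A carry the same information), and anything
else — a gap or an A/G on the forward strand — goes to ``count_other`` and is
excluded from the methylation fraction denominator.  Assay-level summaries are
unweighted means over CpG sites on the 0–100 percent scale; group comparisons
reuse the pooled-variance t-test, classifying each assay as hyper- or
hypomethylated in a lesion group relative to normal adjacent tissue (NAT)
when the shift is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .align import AlignmentResult, AmpliconTemplate

__all__ = [
    "MethylationMatrix",
    "call_cpg_methylation",
    "summarize_assay",
    "build_methylation_matrix",
    "compare_methylation_groups",
    "cluster_markers",
    "plot_heatmap",
]

GROUP_ORDER = ("NAT", "AD", "CRC")
_GROUP_ALIASES = {"normal": "NAT", "adenoma": "AD", "carcinoma": "CRC"}

COMPARISONS = {
    "N_vs_AD": ("NAT", "AD"),
    "N_vs_CRC": ("NAT", "CRC"),
    "AD_vs_CRC": ("AD", "CRC"),
}


def call_cpg_methylation(
    alignments: list[AlignmentResult], template: AmpliconTemplate
) -> pd.DataFrame:
    """Summarize read bases at every unmasked CpG site of one template.

    ``alignments`` must be the passing subset for this template.  Returns a
    DataFrame indexed by (template, position) with columns count_C, count_T,
    count_other, coverage and fraction; fraction is NaN at zero coverage.
    """
    sites = template.unmasked_sites()
    counts = {p: [0, 0, 0] for p in sites}  # C, T, other
    for aln in alignments:
        if aln.template != template.name:
            raise ValueError(
                f"alignment {aln.read_id} is against {aln.template}, "
                f"not {template.name}"
            )
        if aln.passed is False or aln.unalignable:
            raise ValueError("call_cpg_methylation expects passing alignments")
        by_tmpl = {j: i for i, j in aln.pairs if j is not None}
        for p in sites:
            # forward reads show the CpG C itself; reverse-oriented reads show
            # the complementary strand's G (revcomp'd to plus: G at p+1)
            col = p if aln.orientation == "forward" else p + 1
            if not (aln.start <= col < aln.end):
                continue
            i = by_tmpl.get(col)
            base = aln.oriented_read[i] if i is not None else "-"
            if aln.orientation == "forward":
                meth, unmeth = "C", "T"
            else:
                meth, unmeth = "G", "A"
            if base == meth:
                counts[p][0] += 1
            elif base == unmeth:
                counts[p][1] += 1
            else:
                counts[p][2] += 1
    idx = pd.MultiIndex.from_tuples(
        [(template.name, p) for p in sites], names=["template", "position"]
    )
    df = pd.DataFrame(
        [counts[p] for p in sites],
        index=idx,
        columns=["count_C", "count_T", "count_other"],
    )
    df["coverage"] = df["count_C"] + df["count_T"]
    with np.errstate(invalid="ignore"):
        df["fraction"] = np.where(
            df["coverage"] > 0, df["count_C"] / df["coverage"], np.nan
        )
    return df


def summarize_assay(
    table: pd.DataFrame,
    sites: list | None = None,
    coverage_weighted: bool = False,
) -> float:
    """Mean methylation percent of an assay over its CpG sites.

    Unweighted mean of the defined per-site fractions × 100 by default;
    ``coverage_weighted=True`` weights each site by its coverage.  NaN when no
    site has defined fraction.
    """
    sub = table if sites is None else table.loc[sites]
    if len(sub) == 0:
        raise ValueError("empty site subset")
    ok = sub["fraction"].notna()
    if not ok.any():
        return float("nan")
    if coverage_weighted:
        w = sub.loc[ok, "coverage"]
        return float(100.0 * (sub.loc[ok, "fraction"] * w).sum() / w.sum())
    return float(100.0 * sub.loc[ok, "fraction"].mean())


@dataclass
class MethylationMatrix:
    """Assay × sample mean methylation percents with per-sample group labels."""

    values: pd.DataFrame  # assays × samples, percent scale, NaN = missing
    groups: pd.Series  # sample id -> group label (NAT/AD/CRC)

    def __post_init__(self) -> None:
        self.groups = self.groups.replace(_GROUP_ALIASES)
        if not set(self.values.columns) <= set(self.groups.index):
            raise ValueError("every sample column needs a group label")
        bad = ~(self.values.isna() | ((self.values >= 0) & (self.values <= 100)))
        if bad.any().any():
            raise ValueError("methylation percents must lie in [0, 100]")


def build_methylation_matrix(
    per_sample_tables: dict[str, pd.DataFrame],
    groups: pd.Series,
    coverage_weighted: bool = False,
) -> MethylationMatrix:
    """Assemble per-sample CpG call tables into an assay × sample matrix."""
    cols = {}
    for sample, table in per_sample_tables.items():
        cols[sample] = {
            assay: summarize_assay(sub, coverage_weighted=coverage_weighted)
            for assay, sub in table.groupby(level="template")
        }
    values = pd.DataFrame(cols)
    return MethylationMatrix(values, groups)


def compare_methylation_groups(
    matrix: MethylationMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-assay group means ± SD, pairwise p-values and hyper/hypo classes.

    An assay is hypermethylated in a lesion group when its mean exceeds the
    NAT mean with p < alpha (pooled-variance t-test), hypomethylated when
    below with p < alpha, otherwise unchanged; ``not_evaluable`` when a group
    has no measurements.
    """
    rows = []
    for assay in matrix.values.index:
        row: dict = {"assay": assay}
        series = matrix.values.loc[assay]
        by_group = {
            g: series[matrix.groups[series.index] == g].dropna().to_numpy()
            for g in GROUP_ORDER
        }
        for g in GROUP_ORDER:
            row[f"mean_{g}"] = by_group[g].mean() if len(by_group[g]) else np.nan
            row[f"sd_{g}"] = (
                by_group[g].std(ddof=1) if len(by_group[g]) > 1 else np.nan
            )
        for name, (ga, gb) in COMPARISONS.items():
            a, b = by_group[ga], by_group[gb]
            if len(a) < 2 or len(b) < 2:
                row[f"p_{name}"] = np.nan
                continue
            with np.errstate(divide="ignore", invalid="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(a, b, equal_var=True)
            p = float(res.pvalue)
            row[f"p_{name}"] = 1.0 if np.isnan(res.statistic) else p
        for lesion, comp in (("AD", "N_vs_AD"), ("CRC", "N_vs_CRC")):
            p = row[f"p_{comp}"]
            if np.isnan(row["mean_NAT"]) or np.isnan(row[f"mean_{lesion}"]) or np.isnan(p):
                cls = "not_evaluable"
            elif p < alpha and row[f"mean_{lesion}"] > row["mean_NAT"]:
                cls = "hypermethylated"
            elif p < alpha and row[f"mean_{lesion}"] < row["mean_NAT"]:
                cls = "hypomethylated"
            else:
                cls = "unchanged"
            row[f"class_{lesion}"] = cls
        rows.append(row)
    return pd.DataFrame(rows).set_index("assay")


def cluster_markers(
    matrix: MethylationMatrix,
    distance: str = "euclidean",
    linkage: str = "average",
    k: int | None = None,
) -> dict:
    """Hierarchical clustering of assays (rows) and samples (columns).

    Missing cells are mean-imputed per row before computing distances; rows
    with no observed value are excluded with a warning.  Returns row/column
    leaf orderings, the row linkage matrix, and (when ``k`` is given) a flat
    row partition from cutting the dendrogram into ``k`` groups.
    """
    vals = matrix.values.copy()
    all_missing = vals.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"excluding all-missing assays: {list(vals.index[all_missing])}"
        )
        vals = vals.loc[~all_missing]
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 assays with data to cluster")
    filled = vals.apply(lambda r: r.fillna(r.mean()), axis=1)
    # sort for input-order invariance; report in (sorted) index coordinates
    filled = filled.sort_index()
    row_link = hierarchy.linkage(
        pdist(filled.to_numpy(), metric=distance), method=linkage
    )
    if filled.shape[1] >= 2:
        col_link = hierarchy.linkage(
            pdist(filled.to_numpy().T, metric=distance), method=linkage
        )
        col_order = [filled.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link = None
        col_order = list(filled.columns)
    out = {
        "row_order": [filled.index[i] for i in hierarchy.leaves_list(row_link)],
        "col_order": col_order,
        "row_linkage": row_link,
        "col_linkage": col_link,
        "assays": list(filled.index),
    }
    if k is not None:
        labels = hierarchy.fcluster(row_link, t=k, criterion="maxclust")
        out["row_clusters"] = dict(zip(filled.index, (int(x) for x in labels)))
    return out


def plot_heatmap(matrix: MethylationMatrix, path: str, clustering: dict | None = None):
    """Write a clustered methylation heatmap image (optional convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clustering = clustering or cluster_markers(matrix)
    vals = matrix.values.loc[clustering["row_order"], clustering["col_order"]]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * vals.shape[1]),
                                    max(3, 0.3 * vals.shape[0])))
    im = ax.imshow(vals.to_numpy(), aspect="auto", cmap="RdYlGn_r",
                   vmin=0, vmax=100)
    ax.set_xticks(range(vals.shape[1]), vals.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(vals.shape[0]), vals.index, fontsize=6)
    fig.colorbar(im, label="methylation %")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
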