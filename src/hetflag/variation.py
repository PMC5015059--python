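"""Coefficient-of-variation comparison between lncRNAs and mRNAs.

For every expressed gene (max FPKM strictly above the positivity
threshold) the CV of its expression *across all cells, zeros included* is
computed — excluding zero cells would conflate the CV with the
expressing-cell count.  Genes are stratified by their maximum expression
into a moderate (threshold < max ≤ upper bound, default 3–30 FPKM) and a
high (> upper bound) stratum, and the four biotype × stratum groups are
compared with Welch's unequal-variance t-test, two-sided.

The CV uses the sample (n−1) standard deviation; with that convention a
gene expressed at any level v in exactly one of C cells has CV exactly
√C, an identity the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, HetflagError
from .heterogeneity import AnalysisConfig
from .quantification import ExpressionMatrix


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """Sample SD / mean across all cells (zeros included)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateDataError("CV needs at least 2 cells")
    mean = arr.mean()
    if mean <= 0:
        raise HetflagError("CV undefined for non-expressed gene (mean <= 0)")
    return float(arr.std(ddof=ddof) / mean)


def stratify_expressed_genes(matrix: ExpressionMatrix,
                             biotypes: Mapping[str, str],
                             config: AnalysisConfig = AnalysisConfig(),
                             ddof: int = 1) -> pd.DataFrame:
    """Per-gene CV records for expressed genes of known biotype.

    Returns a DataFrame with columns gene_id, biotype, stratum
    ('moderate' or 'high'), max_fpkm, cv.
    """
    maxes = matrix.values.max(axis=1)
    rows = []
    for i, gid in enumerate(matrix.genes):
        bt = biotypes.get(gid)
        if bt not in ("coding", "noncoding"):
            continue
        if maxes[i] <= config.expr_threshold:
            continue
        stratum = "moderate" if maxes[i] <= config.window_high else "high"
        rows.append({
            "gene_id": gid, "biotype": bt, "stratum": stratum,
            "max_fpkm": maxes[i],
            "cv": coefficient_of_variation(matrix.values[i], ddof=ddof),
        })
    return pd.DataFrame(rows, columns=["gene_id", "biotype", "stratum",
                                       "max_fpkm", "cv"])


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float


def welch_test(x, y) -> WelchResult:
    """Two-sided Welch (unequal-variance) t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("each sample needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise DegenerateDataError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        n_x=int(x.size), n_y=int(y.size),
        mean_x=float(x.mean()), mean_y=float(y.mean()),
    )


GROUP_ORDER = [("coding", "high"), ("noncoding", "high"),
               ("coding", "moderate"), ("noncoding", "moderate")]


def _group_label(biotype: str, stratum: str) -> str:
    name = "mRNA" if biotype == "coding" else "lncRNA"
    return f"{name}-{stratum}"


def pairwise_cv_comparisons(records: pd.DataFrame) -> pd.DataFrame:
    """All 6 Welch tests among the biotype × stratum groups.

    Raises if any group is empty.  Degenerate pairs (both groups constant)
    surface as errors rather than NaNs.
    """
    groups: dict[str, np.ndarray] = {}
    for bt, stratum in GROUP_ORDER:
        sub = records[(records["biotype"] == bt) & (records["stratum"] == stratum)]
        label = _group_label(bt, stratum)
        if sub.empty:
            raise DegenerateDataError(f"group {label} is empty")
        groups[label] = sub["cv"].to_numpy()
    rows = []
    for (la, xa), (lb, xb) in combinations(groups.items(), 2):
        res = welch_test(xa, xb)
        rows.append({
            "group_a": la, "group_b": lb,
            "t": res.t_statistic, "df": res.degrees_of_freedom,
            "p": res.p_value, "n_a": res.n_x, "n_b": res.n_y,
            "mean_a": res.mean_x, "mean_b": res.mean_y,
        })
    return pd.DataFrame(rows)


def boxplot_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics per group: quartiles, median and 1.5×IQR
    whiskers (whisker ends clamped to the most extreme point inside the
    fence), plus the outlier count."""
    rows = []
    for bt, stratum in GROUP_ORDER:
        sub = records[(records["biotype"] == bt) & (records["stratum"] == stratum)]
        if sub.empty:
            continue
        cv = sub["cv"].to_numpy()
        q1, med, q3 = np.percentile(cv, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = cv[(cv >= lo_fence) & (cv <= hi_fence)]
        rows.append({
            "group": _group_label(bt, stratum), "n": cv.size,
            "q1": q1, "median": med, "q3": q3,
            "whisker_lo": inside.min() if inside.size else np.nan,
            "whisker_hi": inside.max() if inside.size else np.nan,
            "n_outliers": int(((cv < lo_fence) | (cv > hi_fence)).sum()),
        })
    return pd.DataFrame(rows)
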