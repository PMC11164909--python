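"""Comparative statistics across cells and conditions.

Group comparisons use the non-parametric Mann-Whitney U test with a
two-tailed p-value, computed on *per-cell* metric values (cells are the
statistical units, matching how per-cell averages are compared between
quiescent and activated arms).  The exact null distribution is used for
small tie-free problems (n*m <= 400); larger or tied problems use the
normal approximation with tie and continuity corrections.  Associations
between per-cell metrics use the Pearson product-moment correlation with a
t-transform p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_LIMIT = 400  # exact MWU when n*m <= this and no ties


@dataclass
class ComparisonResult:
    u_statistic: float
    p_value: float  # two-tailed
    n_x: int
    n_y: int
    median_x: float
    median_y: float
    method: str = "exact"

    @property
    def direction(self) -> str:
        if self.median_x > self.median_y:
            return "x>y"
        if self.median_x < self.median_y:
            return "x<y"
        return "x=y"


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic of ``x`` (midranks under ties).  Exact
    enumeration p when n*m <= 400 with no ties, else the tie-corrected,
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = x.size * y.size <= EXACT_LIMIT and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_x=x.size,
        n_y=y.size,
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
        method="exact" if exact else "asymptotic",
    )


def pearson_r(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed t-transform p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=x.size, p_value=float(res.pvalue))


def compare_conditions(
    records: pd.DataFrame,
    metric: str,
    group: str = "condition",
) -> tuple[ComparisonResult, pd.DataFrame]:
    """Mann-Whitney comparison of a per-cell metric between two conditions.

    Cells with an undefined (NaN) metric are excluded (count logged).
    Returns the test result (x = first condition in sorted label order) and
    a per-condition summary table (n, median, IQR).
    """
    if metric not in records.columns:
        raise ValueError(f"metric {metric!r} not in records")
    labels = sorted(records[group].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 conditions, found {labels}")
    groups = {}
    for lab in labels:
        vals = records.loc[records[group] == lab, metric].to_numpy(float)
        ok = np.isfinite(vals)
        if (~ok).sum():
            logger.info("condition %s: excluded %d cells with undefined %s", lab, (~ok).sum(), metric)
        vals = vals[ok]
        if vals.size == 0:
            raise ValueError(f"condition {lab!r} has no usable cells for {metric!r}")
        groups[lab] = vals
    result = mann_whitney_u(groups[labels[0]], groups[labels[1]])
    summary = pd.DataFrame(
        {
            group: labels,
            "n": [groups[l].size for l in labels],
            "median": [float(np.median(groups[l])) for l in labels],
            "iqr_low": [float(np.percentile(groups[l], 25)) for l in labels],
            "iqr_high": [float(np.percentile(groups[l], 75)) for l in labels],
        }
    )
    return result, summary


def correlate_nuclear_cytosolic(
    records: pd.DataFrame,
    size_col: str = "mean_fwhm_nm",
    cyto_size_col: str = "mean_cyto_fwhm_nm",
    cyto_count_col: str = "n_cytosolic_clusters",
) -> tuple[CorrelationResult, CorrelationResult]:
    """Per-cell correlations of nuclear domain size with cytosolic cluster
    size and with cytosolic cluster count (the two release-coupling readouts).
    Cells lacking cytosolic clusters are excluded from the size correlation.
    """
    size = records[[size_col, cyto_size_col]].dropna()
    if len(size) < 3:
        raise ValueError("need >= 3 cells with defined cytosolic size")
    r_size = pearson_r(size[size_col], size[cyto_size_col])
    count = records[[size_col, cyto_count_col]].dropna()
    if len(count) < 3:
        raise ValueError("need >= 3 cells with defined cytosolic count")
    r_count = pearson_r(count[size_col], count[cyto_count_col])
    return r_size, r_count
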