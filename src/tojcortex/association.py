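"""Region-wise association of cortical metrics with judgment reversal.

Pearson correlations per atlas region with Benjamini-Hochberg FDR
control across the 68 regional tests (one family per metric), plus the
Wilcoxon rank-sum comparison between groups (e.g. the sexes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_r_p", "bh_fdr", "screen_regions", "rank_sum_test", "ScreenResult"]


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q for the i-th smallest p is min over j >= i of p_(j) * m / j; the
    adjustment is order-preserving and q >= p elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a region-by-region correlation screen for one metric."""

    metric: str
    outcome: str
    table: pd.DataFrame  # region, metric, r, p, q, significant
    fdr_level: float

    @property
    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "region"])


def screen_regions(
    metric_table: pd.DataFrame,
    outcome: pd.Series,
    metric: str = "mct",
    fdr_level: float = 0.05,
    outcome_name: str = "reversal_value",
) -> ScreenResult:
    """Correlate one cortical metric with a per-subject outcome per region.

    Parameters
    ----------
    metric_table
        Long-format region metrics with columns ``subject``, ``region``
        and the metric column (as produced by
        :func:`tojcortex.morphometry.region_metrics` over a cohort).
    outcome
        Per-subject outcome indexed by subject id — typically the
        reversal value, or the mean peak flip for the re-analysis that
        isolates the pure degree of peak judgment reversal.

    The p-values of the per-region correlations are adjusted across
    exactly the regions screened (one FDR family per metric); a region is
    significant when q <= ``fdr_level``.
    """
    for col in ("subject", "region", metric):
        if col not in metric_table.columns:
            raise ValueError(f"metric table lacks column {col!r}")
    wide = metric_table.pivot(index="subject", columns="region", values=metric)
    if wide.isna().any().any():
        raise ValueError("subject/region combinations are incomplete")
    missing = set(wide.index).symmetric_difference(set(outcome.index))
    if missing:
        raise ValueError(f"subject mismatch between metrics and outcome: {sorted(missing)[:3]}")
    y = outcome.loc[wide.index].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 subjects")

    regions = list(wide.columns)
    r = np.empty(len(regions))
    p = np.empty(len(regions))
    for i, region in enumerate(regions):
        r[i], p[i] = pearson_r_p(wide[region].to_numpy(), y)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "region": regions,
            "metric": metric,
            "r": r,
            "p": p,
            "q": q,
            "significant": q <= fdr_level,
        }
    )
    return ScreenResult(metric=metric, outcome=outcome_name, table=table, fdr_level=fdr_level)


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a location difference.

    Exact when both groups have n <= 10 and there are no ties; otherwise
    the normal approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    exact = a.size <= 10 and b.size <= 10 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)
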