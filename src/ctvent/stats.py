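"""Cohort statistics: normality-gated paired and group comparisons, and
Table-style mean +/- SD summaries with significance markers.

Each comparison first applies a Shapiro-Wilk normality gate at alpha=0.05
(on the paired differences, or per group), then picks the parametric or
rank-based two-tailed test accordingly:

    paired:   normal -> paired t-test,  else -> Wilcoxon signed-rank
    unpaired: normal -> two-sample t,   else -> Wilcoxon rank-sum

Significance is marked at p < 0.05 (*) and p < 0.01 (**) per comparison;
no multiple-testing correction is applied (metrics are reported
per-comparison, as is conventional in planning-study tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "paired_compare", "group_compare", "summarize"]

ALPHA_NORMALITY = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    strategy_pair: tuple[str, str]
    test_used: str  # paired_t | wilcoxon_signed_rank | rank_sum_paired | unpaired_t | rank_sum
    statistic: float
    p_value: float
    mean_sd_a: tuple[float, float]
    mean_sd_b: tuple[float, float]
    normal: bool
    degenerate: bool = False

    @property
    def significance(self) -> str:
        if self.degenerate:
            return ""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def _shapiro_normal(x: np.ndarray) -> bool:
    # Shapiro-Wilk needs n >= 3 and non-constant input; constant or tiny
    # samples fail the gate (fall through to the rank test)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > ALPHA_NORMALITY


def paired_compare(
    values_a,
    values_b,
    metric: str = "",
    pair: tuple[str, str] = ("a", "b"),
    use_literal_rank_sum: bool = False,
) -> ComparisonResult:
    """Two-tailed paired comparison with a normality gate on the differences.

    ``use_literal_rank_sum`` replaces the signed-rank test with an
    (unpaired) Wilcoxon rank-sum on the two samples, for parity with
    reports that quote a rank-sum test in a paired setting.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("paired comparison needs n >= 3")
    diff = b - a
    if np.all(diff == 0):
        return ComparisonResult(
            metric, pair, "degenerate", 0.0, 1.0, _mean_sd(a), _mean_sd(b),
            normal=False, degenerate=True,
        )
    normal = _shapiro_normal(diff)
    if normal:
        res = sps.ttest_rel(a, b)
        test = "paired_t"
    elif use_literal_rank_sum:
        res = sps.ranksums(a, b)
        test = "rank_sum_paired"
    else:
        res = sps.wilcoxon(a, b, zero_method="wilcox")
        test = "wilcoxon_signed_rank"
    return ComparisonResult(
        metric, pair, test, float(res.statistic), float(res.pvalue),
        _mean_sd(a), _mean_sd(b), normal=normal,
    )


def group_compare(
    values_g1,
    values_g2,
    metric: str = "",
    pair: tuple[str, str] = ("group1", "group2"),
) -> ComparisonResult:
    """Two-tailed unpaired comparison with a per-group normality gate."""
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1[0] == g2[0]:
        return ComparisonResult(
            metric, pair, "degenerate", 0.0, 1.0, _mean_sd(g1), _mean_sd(g2),
            normal=False, degenerate=True,
        )
    normal = _shapiro_normal(g1) and _shapiro_normal(g2)
    if normal:
        res = sps.ttest_ind(g1, g2)
        test = "unpaired_t"
    else:
        res = sps.ranksums(g1, g2)
        test = "rank_sum"
    return ComparisonResult(
        metric, pair, test, float(res.statistic), float(res.pvalue),
        _mean_sd(g1), _mean_sd(g2), normal=normal,
    )


def summarize(
    metrics: pd.DataFrame,
    strategies: tuple[str, ...] | None = None,
    reference_strategy: str = "anatomical",
) -> pd.DataFrame:
    """Mean +/- SD summary per (metric, strategy) with significance vs the
    anatomical column.

    ``metrics`` is a tidy frame with columns (patient, strategy, metric,
    value); the result has one row per metric and one block of columns
    (mean, sd, p, sig) per strategy.  With a single patient the SD is 0 and
    no test is run.
    """
    required = {"patient", "strategy", "metric", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame must have columns {sorted(required)}")
    if strategies is None:
        strategies = tuple(pd.unique(metrics["strategy"]))
    wide = metrics.pivot_table(
        index=["metric", "patient"], columns="strategy", values="value"
    )
    rows = []
    for metric_name, block in wide.groupby(level="metric"):
        row: dict[str, object] = {"metric": metric_name}
        ref = block[reference_strategy].to_numpy() if reference_strategy in block else None
        for strat in strategies:
            if strat not in block:
                continue
            vals = block[strat].dropna().to_numpy()
            m, s = _mean_sd(vals)
            row[f"{strat}_mean"] = m
            row[f"{strat}_sd"] = s
            if strat != reference_strategy and ref is not None and vals.size >= 3:
                cmp = paired_compare(
                    ref, vals, metric=str(metric_name),
                    pair=(reference_strategy, strat),
                )
                row[f"{strat}_p"] = cmp.p_value
                row[f"{strat}_sig"] = cmp.significance
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def render_summary(summary: pd.DataFrame, strategies: tuple[str, ...]) -> str:
    """Plain-text rendering of a summary table (mean +/- SD with markers)."""
    lines = []
    header = ["metric"] + list(strategies)
    widths = [24] + [20] * len(strategies)
    lines.append("".join(h.ljust(w) for h, w in zip(header, widths)))
    for metric_name, row in summary.iterrows():
        cells = [str(metric_name).ljust(widths[0])]
        for strat, w in zip(strategies, widths[1:]):
            if f"{strat}_mean" not in row or pd.isna(row.get(f"{strat}_mean")):
                cells.append("-".ljust(w))
                continue
            sig = row.get(f"{strat}_sig", "")
            sig = "" if pd.isna(sig) else sig
            cells.append(
                f"{row[f'{strat}_mean']:.2f} ± {row[f'{strat}_sd']:.2f}{sig}".ljust(w)
            )
        lines.append("".join(cells))
    return "\n".join(lines)
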