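"""Nonparametric group statistics on per-cell metrics.

Two comparison kinds mirror the study design: a paired Wilcoxon
signed-rank test of each cell's original metric against the median of its
own shuffled surrogates, and unpaired Mann-Whitney tests between the
normal and parkinsonian (MPTP) states. Summaries are medians with
interquartile ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("spikeseq")

ALPHA = 0.05

#: Zero-difference convention for the signed-rank test: "wilcox" discards
#: zero differences, "pratt" keeps them in the ranking.
DEFAULT_ZERO_METHOD = "wilcox"


def wilcoxon_paired(
    values_a: np.ndarray,
    values_b: np.ndarray,
    zero_method: str = DEFAULT_ZERO_METHOD,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(statistic, p)``; ``(nan, nan)`` when every difference is
    zero (no information about a shift).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        logger.warning("wilcoxon_paired: all differences zero; test undefined")
        return float("nan"), float("nan")
    res = stats.wilcoxon(a, b, zero_method=zero_method, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear interpolation)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    q1, q3 = np.percentile(v, [25, 75])
    return float(np.median(v)), float(q3 - q1)


@dataclass
class GroupComparison:
    metric: str
    structure: str
    kind: str  # "paired_vs_null" or "normal_vs_mptp"
    state: str  # state for paired comparisons, "" for cross-state
    statistic: float
    p_value: float
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def run_group_table(
    summaries: pd.DataFrame,
    metrics: list[str] | None = None,
    zero_method: str = DEFAULT_ZERO_METHOD,
) -> pd.DataFrame:
    """All paired-vs-null and normal-vs-MPTP comparisons, one row each.

    For every metric and structure: a paired Wilcoxon test of original
    values against the per-cell null medians (separately per state, using
    the ``<metric>_null_median`` column when present), and an unpaired
    Mann-Whitney test between states. Groups with fewer than two usable
    cells are skipped with a warning. P-values are reported raw (no
    multiple-testing correction); ``n_tests`` lets users adjust.
    """
    if metrics is None:
        metrics = [
            c
            for c in summaries.columns
            if f"{c}_null_median" in summaries.columns or c in ("prop_isis_in_seq",)
        ]
    comparisons: list[GroupComparison] = []
    for metric in metrics:
        null_col = f"{metric}_null_median"
        for structure, sgrp in summaries.groupby("structure"):
            if null_col in sgrp.columns:
                for state, grp in sgrp.groupby("state"):
                    sub = grp[[metric, null_col]].dropna()
                    if len(sub) < 2:
                        logger.warning(
                            "skipping paired test %s/%s/%s: n=%d",
                            metric, structure, state, len(sub),
                        )
                        continue
                    stat, p = wilcoxon_paired(
                        sub[metric].to_numpy(),
                        sub[null_col].to_numpy(),
                        zero_method=zero_method,
                    )
                    med_a, iqr_a = median_iqr(sub[metric].to_numpy())
                    med_b, iqr_b = median_iqr(sub[null_col].to_numpy())
                    comparisons.append(
                        GroupComparison(
                            metric=metric, structure=str(structure),
                            kind="paired_vs_null", state=str(state),
                            statistic=stat, p_value=p,
                            median_a=med_a, iqr_a=iqr_a,
                            median_b=med_b, iqr_b=iqr_b,
                            n_a=len(sub), n_b=len(sub),
                        )
                    )
            normal = sgrp.loc[sgrp["state"] == "normal", metric].dropna()
            mptp = sgrp.loc[sgrp["state"] == "MPTP", metric].dropna()
            if len(normal) < 2 or len(mptp) < 2:
                logger.warning(
                    "skipping cross-state test %s/%s: n=%d/%d",
                    metric, structure, len(normal), len(mptp),
                )
            else:
                stat, p = mann_whitney(normal.to_numpy(), mptp.to_numpy())
                med_a, iqr_a = median_iqr(normal.to_numpy())
                med_b, iqr_b = median_iqr(mptp.to_numpy())
                comparisons.append(
                    GroupComparison(
                        metric=metric, structure=str(structure),
                        kind="normal_vs_mptp", state="",
                        statistic=stat, p_value=p,
                        median_a=med_a, iqr_a=iqr_a,
                        median_b=med_b, iqr_b=iqr_b,
                        n_a=len(normal), n_b=len(mptp),
                    )
                )
    table = pd.DataFrame([c.__dict__ | {"significant": c.significant} for c in comparisons])
    if not table.empty:
        table["n_tests"] = len(table)
    return table


def summary_table_markdown(summaries: pd.DataFrame, metrics: list[str]) -> str:
    """Median (IQR) per structure/state plus the cross-state Mann-Whitney p."""
    lines = ["| Metric | Structure | normal | MPTP | MW p |", "|---|---|---|---|---|"]
    for metric in metrics:
        for structure, sgrp in summaries.groupby("structure"):
            cells = {}
            for state in ("normal", "MPTP"):
                vals = sgrp.loc[sgrp["state"] == state, metric].dropna().to_numpy()
                if vals.size:
                    med, iqr = median_iqr(vals)
                    cells[state] = f"{med:.3g} ({iqr:.3g})"
                else:
                    cells[state] = "-"
            normal = sgrp.loc[sgrp["state"] == "normal", metric].dropna()
            mptp = sgrp.loc[sgrp["state"] == "MPTP", metric].dropna()
            if len(normal) >= 2 and len(mptp) >= 2:
                _, p = mann_whitney(normal.to_numpy(), mptp.to_numpy())
                p_str = f"{p:.3g}"
            else:
                p_str = "-"
            lines.append(
                f"| {metric} | {structure} | {cells['normal']} | {cells['MPTP']} | {p_str} |"
            )
    return "\n".join(lines)
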