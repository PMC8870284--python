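"""Group-level comparison of network measures.

The two cohorts are compared per measure and state with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test: exact null distribution for small
tie-free samples (min(n) <= 8), normal approximation with tie correction
otherwise.  Comparisons run on network-level scalars averaged over epochs
per subject, so subjects — not epochs — are the independent units.  No
multiple-testing correction is applied by default; Benjamini-Hochberg is
available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import METRIC_NAMES, MetricSet

__all__ = ["GroupComparison", "rank_sum_test", "compare_groups", "comparisons_to_frame"]


@dataclass
class GroupComparison:
    """Outcome of one rank-sum comparison (one measure, one state)."""

    metric_name: str
    state: str
    statistic: float  # rank sum of the first sample (midranks)
    p_value: float
    direction: int  # sign of (elderly median - middle-aged median)
    significant: bool
    alpha: float = 0.05


def rank_sum_test(
    a, b, alpha: float = 0.05, metric_name: str = "", state: str = ""
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test of samples ``a`` vs ``b``.

    ``a`` is conventionally the elderly-like group, so ``direction`` < 0
    means the measure is lower in that group.  The reported statistic is
    the midrank sum of ``a``.  Identical pooled values yield p = 1 with a
    warning rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    direction = int(np.sign(np.median(a) - np.median(b)))

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p set to 1")
        p = 1.0
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    return GroupComparison(
        metric_name=metric_name,
        state=state,
        statistic=w,
        p_value=p,
        direction=direction,
        significant=p < alpha,
        alpha=alpha,
    )


def _subject_means(metric_sets: list[MetricSet]) -> pd.DataFrame:
    rows = []
    for ms in metric_sets:
        row = {
            "subject_id": ms.subject_id,
            "group": ms.group,
            "state": ms.state,
            "epoch": ms.epoch_index,
        }
        row.update(ms.network_scalars())
        rows.append(row)
    frame = pd.DataFrame(rows)
    # NaN assortativity (degree-regular epochs) is dropped from the epoch
    # average rather than imputed: the test compares real values only.
    return (
        frame.groupby(["subject_id", "group", "state"], as_index=False)[
            list(METRIC_NAMES)
        ].mean()
    )


def compare_groups(
    metric_sets: list[MetricSet],
    alpha: float = 0.05,
    per_epoch: bool = False,
    fdr: bool = False,
) -> list[GroupComparison]:
    """One rank-sum comparison per (measure, state) between the groups.

    Elderly is the first sample throughout, so negative directions read
    "lower in the elderly-like group".  ``per_epoch=True`` compares
    epoch-level values instead of per-subject epoch means. ``fdr`` applies
    Benjamini-Hochberg across all comparisons (off by default).
    """
    if per_epoch:
        rows = []
        for ms in metric_sets:
            row = {"group": ms.group, "state": ms.state}
            row.update(ms.network_scalars())
            rows.append(row)
        table = pd.DataFrame(rows)
    else:
        table = _subject_means(metric_sets)

    groups = set(table["group"])
    missing = {"middle_aged", "elderly"} - groups
    if missing:
        raise ValueError(f"missing group(s) in input: {sorted(missing)}")

    results = []
    for state in sorted(set(table["state"])):
        sub = table[table["state"] == state]
        for metric in METRIC_NAMES:
            a = sub.loc[sub["group"] == "elderly", metric].dropna().to_numpy()
            b = sub.loc[sub["group"] == "middle_aged", metric].dropna().to_numpy()
            results.append(
                rank_sum_test(a, b, alpha=alpha, metric_name=metric, state=state)
            )

    if fdr and results:
        from statsmodels.stats.multitest import multipletests

        rej, p_adj, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, p, flag in zip(results, p_adj, rej):
            r.p_value = float(p)
            r.significant = bool(flag)
    return results


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Results table: metric, state, statistic, p, direction, significant."""
    return pd.DataFrame(
        [
            {
                "metric": r.metric_name,
                "state": r.state,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )
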