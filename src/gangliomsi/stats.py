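"""Group-level inference: one-way ANOVA with Tukey HSD, and count summaries.

Ratios are analyzed per ion channel and per timepoint on their natural
scale by default (an optional log transform is available for the
right-skewed case).  Alpha defaults to 0.05 with no additional multiplicity
correction across ion channels: each channel is treated as its own planned
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "ComparisonResult",
    "StatsError",
    "anova_tukey",
    "anova_tukey_by",
    "percent_reduction",
    "timecourse_test",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonResult:
    """One Tukey-adjusted pairwise group comparison."""

    measure: str
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float
    significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus one-way ANOVA with its Tukey post-hoc comparisons."""

    measure: str
    f_statistic: float
    p_value: float
    comparisons: tuple[ComparisonResult, ...]

    def comparison(self, group_a: str, group_b: str) -> ComparisonResult:
        wanted = {group_a, group_b}
        for comp in self.comparisons:
            if {comp.group_a, comp.group_b} == wanted:
                return comp
        raise KeyError(f"no comparison between {group_a!r} and {group_b!r}")


def _validate_cells(values: np.ndarray, labels: np.ndarray) -> None:
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise StatsError("ANOVA needs at least two groups")
    small = groups[counts < 2]
    if small.size:
        raise StatsError(
            f"groups with fewer than 2 observations: {', '.join(map(str, small))}"
        )


def anova_tukey(
    data: pd.DataFrame,
    value_col: str = "ratio",
    group_col: str = "group",
    alpha: float = 0.05,
    measure: str = "",
    log_scale: bool = False,
) -> AnovaResult:
    """One-way ANOVA across group cells followed by Tukey's HSD for all pairs.

    Rows with missing values are dropped before validation.  With
    ``log_scale`` the response is log-transformed first (values must be
    positive).
    """
    frame = data[[group_col, value_col]].dropna()
    values = frame[value_col].to_numpy(dtype=float)
    labels = frame[group_col].to_numpy()
    if log_scale:
        if np.any(values <= 0):
            raise StatsError("log-scale analysis requires strictly positive values")
        values = np.log(values)
    _validate_cells(values, labels)

    groups = [values[labels == g] for g in np.unique(labels)]
    f_stat, p_val = sps.f_oneway(*groups)

    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = tukey.summary().data[1:]
    comparisons = []
    for row, p_adj in zip(table, np.atleast_1d(tukey.pvalues)):
        group_a, group_b, meandiff = str(row[0]), str(row[1]), float(row[2])
        p_adj = float(min(max(p_adj, 0.0), 1.0))
        comparisons.append(
            ComparisonResult(
                measure=measure,
                group_a=group_a,
                group_b=group_b,
                mean_difference=meandiff,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
                alpha=alpha,
            )
        )
    return AnovaResult(
        measure=measure,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        comparisons=tuple(comparisons),
    )


def anova_tukey_by(
    data: pd.DataFrame,
    by: tuple[str, ...] = ("ion_label", "timepoint_days"),
    value_col: str = "ratio",
    group_col: str = "group",
    alpha: float = 0.05,
    log_scale: bool = False,
) -> dict[tuple, AnovaResult]:
    """Run one independent ANOVA/Tukey per cell of the ``by`` columns.

    Matches the per-panel analysis design: one model per ion channel per
    timepoint, each with its own post-hoc family.
    """
    results: dict[tuple, AnovaResult] = {}
    for key, cell in data.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        measure = "/".join(str(k) for k in key)
        results[key] = anova_tukey(
            cell, value_col=value_col, group_col=group_col, alpha=alpha,
            measure=measure, log_scale=log_scale,
        )
    return results


def percent_reduction(
    table: pd.DataFrame,
    group: str,
    stain: str,
    from_days: int = 3,
    to_days: int = 21,
) -> float:
    """Percent reduction in mean cell count between two timepoints.

    ``100 * (mean_early - mean_late) / mean_early`` for one group and stain;
    positive values mean the count dropped.
    """
    cell = table[(table["group"] == group) & (table["stain"] == stain)]
    early = cell.loc[cell["timepoint_days"] == from_days, "count"]
    late = cell.loc[cell["timepoint_days"] == to_days, "count"]
    if early.empty or late.empty:
        raise StatsError(
            f"both timepoints {from_days} d and {to_days} d are required for "
            f"group {group!r}, stain {stain!r}"
        )
    mean_early = float(early.mean())
    if mean_early == 0:
        raise StatsError(
            f"percent reduction undefined: mean {from_days} d count is zero "
            f"for group {group!r}, stain {stain!r}"
        )
    return 100.0 * (mean_early - float(late.mean())) / mean_early


def timecourse_test(
    data: pd.DataFrame,
    ion_label: str,
    group: str,
    value_col: str = "ratio",
    alpha: float = 0.05,
    log_scale: bool = False,
) -> ComparisonResult:
    """3 d vs 21 d contrast for one group on one ion channel.

    Implemented as the Tukey pair between that group's two timepoint cells
    within a one-way ANOVA over all group x timepoint cells of the channel,
    so the contrast shares the pooled error and the Tukey family with the
    rest of the design.
    """
    channel = data[data["ion_label"] == ion_label].dropna(subset=[value_col]).copy()
    if channel.empty:
        raise StatsError(f"no records for ion channel {ion_label!r}")
    channel["cell"] = channel["group"].astype(str) + "@" + channel["timepoint_days"].astype(str) + "d"
    wanted = {f"{group}@3d", f"{group}@21d"}
    present = set(channel["cell"])
    if not wanted <= present:
        raise StatsError(
            f"group {group!r} needs records at both 3 d and 21 d on {ion_label!r}"
        )
    result = anova_tukey(
        channel, value_col=value_col, group_col="cell", alpha=alpha,
        measure=f"{ion_label}:{group}:3d-vs-21d", log_scale=log_scale,
    )
    return result.comparison(f"{group}@3d", f"{group}@21d")
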