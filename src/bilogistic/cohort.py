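"""Replicate-level parameter aggregation and between-group comparison.

Fitting each replicate separately turns a stack of survival curves into a
table of shape parameters (f, k, t1, t2, ...), which can then be analysed
like any other quantitative trait: per-group mean ± s.e.m., one-way ANOVA
across groups, and Tukey HSD pairwise comparisons with the usual
significance stars.  This is how lifespan modifiers (temperature, a FOXO
mutation) are read off the model parameters rather than off whole curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .fitting import FitResult

__all__ = ["CohortSummary", "GroupComparison", "summarize_replicates", "compare_groups", "stars"]


def stars(p: float) -> str:
    """Significance stars at p < 0.05, 0.01, 0.001, 0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class CohortSummary:
    """Per-replicate parameter estimates for one experimental group."""

    group: str
    model_id: str
    table: pd.DataFrame  # index: replicate, columns: parameter symbols
    means: pd.Series
    sems: pd.Series

    @property
    def n(self) -> int:
        return len(self.table)


def summarize_replicates(fits: Sequence[FitResult], group: str) -> CohortSummary:
    """Aggregate converged per-replicate fits into mean ± s.e.m. per parameter.

    All fits must share one model; non-converged fits are excluded with a
    warning (never imputed).  A single-replicate group reports s.e.m. 0.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    model_ids = {f.model_id for f in fits}
    if len(model_ids) > 1:
        raise ValueError(f"mixed models in one cohort: {sorted(model_ids)}")
    kept = [f for f in fits if f.converged]
    dropped = len(fits) - len(kept)
    if dropped:
        warnings.warn(f"excluding {dropped} non-converged fit(s) from group {group!r}")
    if not kept:
        raise ValueError(f"no converged fits in group {group!r}")
    table = pd.DataFrame(
        [f.params.as_dict() for f in kept],
        index=[f"rep{i + 1}" for i in range(len(kept))],
    )
    n = len(table)
    means = table.mean()
    sems = table.std(ddof=1) / math.sqrt(n) if n > 1 else table.iloc[0] * 0.0
    return CohortSummary(
        group=group, model_id=fits[0].model_id, table=table, means=means, sems=sems
    )


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD for one model parameter across groups."""

    parameter: str
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, adj_p, stars

    def to_frame(self) -> pd.DataFrame:
        out = self.pairwise.copy()
        out.insert(0, "parameter", self.parameter)
        return out


def compare_groups(
    summaries: Sequence[CohortSummary], parameter: str
) -> GroupComparison:
    """Compare one fitted parameter across experimental groups.

    Runs a one-way ANOVA over the per-replicate values of ``parameter``
    followed by Tukey HSD pairwise comparisons with adjusted p-values.
    Groups with fewer than two replicates are excluded with a warning.
    """
    usable: list[CohortSummary] = []
    for s in summaries:
        if parameter not in s.table.columns:
            raise ValueError(f"parameter {parameter!r} not in group {s.group!r}")
        if s.n < 2:
            warnings.warn(f"group {s.group!r} has < 2 replicates; excluded")
            continue
        usable.append(s)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 replicates")

    samples = [s.table[parameter].to_numpy() for s in usable]
    if np.ptp(np.concatenate(samples)) == 0:
        # identical values everywhere: no variance at all, F is 0 by convention
        f_stat, p_val = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_val = stats.f_oneway(*samples)
        if not np.isfinite(f_stat):
            f_stat, p_val = 0.0, 1.0

    values = np.concatenate(samples)
    labels = np.concatenate(
        [np.repeat(s.group, s.n) for s in usable]
    )
    if np.ptp(values) == 0:
        pairs = []
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                pairs.append((usable[i].group, usable[j].group, 0.0, 1.0, "ns"))
        pairwise = pd.DataFrame(
            pairs, columns=["group_a", "group_b", "mean_diff", "adj_p", "stars"]
        )
    else:
        tk = pairwise_tukeyhsd(values, labels)
        frame = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
        pairwise = pd.DataFrame(
            {
                "group_a": frame["group1"],
                "group_b": frame["group2"],
                "mean_diff": frame["meandiff"].astype(float),
                "adj_p": frame["p-adj"].astype(float),
            }
        )
        pairwise["stars"] = pairwise["adj_p"].map(stars)
    return GroupComparison(
        parameter=parameter,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pairwise,
    )
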