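"""Model-selection criteria and comparison across replicate lifespan curves.

Two parsimony-adjusted goodness-of-fit measures are used side by side, each
attached to one fitting route: the corrected Akaike information criterion
(AICc) for maximum-likelihood fits, and the adjusted (unbiased) RMSE for
least-squares fits.  Both penalize extra parameters, so the 4- and
5-parameter bilogistic models only win when the data genuinely carry a
biphasic signal.  A binned residual analysis (bins of 2, 3 or 4 days)
exposes systematic deviations that a single scalar criterion can hide.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "aicc",
    "adjusted_rmse",
    "bin_residuals",
    "compare_models",
    "ResidualBinSummary",
    "ModelComparison",
    "ALLOWED_BIN_WIDTHS",
]

logger = logging.getLogger(__name__)

ALLOWED_BIN_WIDTHS = (2, 3, 4)

#: AICc differences below this are reported as ties, not arbitrated.
TIE_TOL = 1e-9


def aicc(aic: float, n_params: int, m: int) -> float:
    """Small-sample corrected AIC: AIC + (2k² + 2k) / (m − k − 1).

    ``m`` is the number of data points in the replicate and ``n_params`` the
    model's parameter count.  Lower values indicate a more reliable fit.

    Raises
    ------
    ValueError
        If ``m <= n_params + 1`` (the correction's denominator vanishes).
    """
    if m <= n_params + 1:
        raise ValueError(
            f"AICc undefined for m={m} data points and k={n_params} parameters "
            "(requires m > k + 1)"
        )
    return aic + (2.0 * n_params**2 + 2.0 * n_params) / (m - n_params - 1)


def adjusted_rmse(residuals: Sequence[float] | np.ndarray, n_params: int) -> float:
    """Unbiased RMSE: sqrt( Σ(yᵢ − ŷᵢ)² / (m − k) ).

    The denominator ``m − k`` charges each fitted parameter one degree of
    freedom, so richer models are penalized.

    Raises
    ------
    ValueError
        If the residual count does not exceed ``n_params``.
    """
    r = np.asarray(residuals, dtype=float)
    m = r.size
    if m <= n_params:
        raise ValueError(
            f"adjusted RMSE undefined for m={m} residuals and k={n_params} parameters"
        )
    return float(np.sqrt(np.sum(r * r) / (m - n_params)))


@dataclass
class ResidualBinSummary:
    """Pooled residuals grouped into fixed-width day bins.

    Bins are half-open intervals ``[start, start + width)`` anchored at day
    0.  With two or more replicates the s.e.m. is taken across the
    replicate-level bin means (sd/√n over replicates); with a single
    replicate it falls back to the s.e.m. of the residuals pooled within the
    bin, and ``single_replicate`` is set.
    """

    bin_width: int
    bins: pd.DataFrame  # columns: start, mean, sem, count
    single_replicate: bool = False

    @property
    def total_count(self) -> int:
        return int(self.bins["count"].sum())


def bin_residuals(
    residuals_by_replicate: Sequence[Sequence[tuple[float, float]]],
    bin_width: int,
) -> ResidualBinSummary:
    """Bin (day, residual) pairs from one or more replicates.

    Parameters
    ----------
    residuals_by_replicate
        One sequence of ``(day, residual)`` pairs per replicate, e.g. the
        ``residuals`` field of a :class:`~bilogistic.fitting.FitResult`.
    bin_width
        2, 3 or 4 days.

    Returns
    -------
    ResidualBinSummary
        Per-bin mean, s.e.m. and pooled count; empty bins inside the
        observed range are emitted with count 0.
    """
    if bin_width not in ALLOWED_BIN_WIDTHS:
        raise ValueError(f"bin_width must be one of {ALLOWED_BIN_WIDTHS}, got {bin_width}")
    reps = [np.asarray(r, dtype=float).reshape(-1, 2) for r in residuals_by_replicate if len(r)]
    if not reps:
        raise ValueError("no residuals to bin")
    pooled = np.concatenate(reps, axis=0)
    max_day = float(pooled[:, 0].max())
    n_bins = int(max_day // bin_width) + 1
    starts = np.arange(n_bins) * bin_width

    rows = []
    single = len(reps) == 1
    for s in starts:
        in_bin = [r[(r[:, 0] >= s) & (r[:, 0] < s + bin_width), 1] for r in reps]
        count = int(sum(v.size for v in in_bin))
        if count == 0:
            rows.append((float(s), np.nan, np.nan, 0))
            continue
        if single:
            vals = in_bin[0]
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        else:
            rep_means = np.array([v.mean() for v in in_bin if v.size > 0])
            mean = float(rep_means.mean())
            n = rep_means.size
            sem = float(rep_means.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append((float(s), mean, sem, count))
    bins = pd.DataFrame(rows, columns=["start", "mean", "sem", "count"])
    return ResidualBinSummary(bin_width=bin_width, bins=bins, single_replicate=single)


@dataclass
class ModelComparison:
    """AICc / adjusted-RMSE table for every (replicate, model) pair."""

    table: pd.DataFrame  # columns: replicate, model, aicc, rmse_adj, converged
    best_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    ties: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)

    def ranking(self, criterion: str = "aicc") -> pd.Series:
        """Models ordered by mean criterion value (ascending: best first)."""
        return self.table.groupby("model")[criterion].mean().sort_values()

    def to_tidy(self) -> pd.DataFrame:
        """(replicate, model, criterion, value) long-format table."""
        return self.table.melt(
            id_vars=["replicate", "model"],
            value_vars=["aicc", "rmse_adj"],
            var_name="criterion",
            value_name="value",
        )

    def best_counts_frame(self) -> pd.DataFrame:
        rows = [
            (crit, model, n)
            for crit, counts in self.best_counts.items()
            for model, n in counts.items()
        ]
        return pd.DataFrame(rows, columns=["criterion", "model", "best_count"])


def compare_models(
    curves: Iterable,
    models: Sequence[str],
    seed: int = 0,
) -> ModelComparison:
    """Fit every replicate curve with every model and tabulate the criteria.

    Each (replicate, model) cell is fitted twice: by maximum likelihood
    (yielding AICc) and by least squares (yielding the adjusted RMSE).  Per
    criterion and replicate the best model is counted; ties within 1e−9 are
    credited to all tied models and recorded in ``ties``.  Cells whose fit
    fails are marked missing and the comparison proceeds.
    """
    from . import fitting  # deferred: fitting uses this module's criteria

    curves = list(curves)
    if not curves or not models:
        raise ValueError("need at least one curve and one model")
    rows = []
    for i, curve in enumerate(curves):
        rep = getattr(curve, "label", None) or f"rep{i}"
        for model_id in models:
            try:
                mle = fitting.fit_mle(curve, model_id, seed=seed)
                ls = fitting.fit_least_squares(curve, model_id, seed=seed)
                rows.append((rep, model_id, mle.aicc, ls.rmse_adj,
                             mle.converged and ls.converged))
            except Exception as exc:  # noqa: BLE001 - cell-level robustness
                logger.warning("fit failed for %s / %s: %s", rep, model_id, exc)
                rows.append((rep, model_id, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["replicate", "model", "aicc", "rmse_adj", "converged"]
    )

    best_counts: dict[str, dict[str, int]] = {}
    ties: list[tuple[str, str, tuple[str, ...]]] = []
    for criterion in ("aicc", "rmse_adj"):
        counts = {m: 0 for m in models}
        for rep, grp in table.groupby("replicate", sort=False):
            vals = grp.set_index("model")[criterion].dropna()
            if vals.empty:
                continue
            lo = vals.min()
            winners = tuple(vals.index[vals <= lo + TIE_TOL])
            for w in winners:
                counts[w] += 1
            if len(winners) > 1:
                ties.append((criterion, str(rep), winners))
        best_counts[criterion] = counts
    return ModelComparison(table=table, best_counts=best_counts, ties=ties)
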