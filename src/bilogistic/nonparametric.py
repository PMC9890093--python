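"""Kaplan–Meier estimation and the log-rank (Mantel–Cox) test.

The non-parametric baseline of any lifespan assay: per-individual event
records (death or right-censoring, scored in days of adulthood) are turned
into a product-limit survival curve, and two curves are compared with the
Mantel–Cox statistic.  Estimation is delegated to ``lifelines``; this module
owns the event-table contract, the percent-scale curve used by the fitting
machinery, and the daily-scoring conventions (deaths processed before
censorings at tied times; curves kept at observed days only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .fitting import SurvivalCurve

__all__ = [
    "EventTable",
    "LogRankResult",
    "kaplan_meier",
    "log_rank",
    "DEATH",
    "CENSORED",
]

DEATH = 1
CENSORED = 0

_STATUS_STRINGS = {"death": DEATH, "dead": DEATH, "censored": CENSORED, "censor": CENSORED}

REQUIRED_COLUMNS = ("time_days", "status", "group", "replicate")


@dataclass
class EventTable:
    """Per-individual lifespan records: (time_days, status, group, replicate).

    ``status`` is 1 for an observed death and 0 for right-censoring; animals
    alive at assay end must be recorded as censored at their last
    observation.  Times are finite and >= 0, labels non-empty.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing column(s) {missing}")
        if len(df) == 0:
            raise ValueError("empty event table")
        df = df.copy()
        df["status"] = df["status"].map(normalize_status)
        t = pd.to_numeric(df["time_days"], errors="coerce")
        bad = df.index[~np.isfinite(t) | (t < 0)].tolist()
        if bad:
            raise ValueError(f"non-finite or negative time_days at rows {bad}")
        df["time_days"] = t.astype(float)
        for col in ("group", "replicate"):
            df[col] = df[col].astype(str)
            if (df[col].str.len() == 0).any():
                raise ValueError(f"empty {col} label")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n0(self) -> int:
        return len(self.data)

    @property
    def n_deaths(self) -> int:
        return int((self.data["status"] == DEATH).sum())

    @classmethod
    def from_records(
        cls,
        times: Sequence[float],
        status: Sequence[int],
        group: str = "all",
        replicate: str = "r1",
    ) -> "EventTable":
        return cls(
            pd.DataFrame(
                {
                    "time_days": list(times),
                    "status": list(status),
                    "group": group,
                    "replicate": replicate,
                }
            )
        )

    def subset(self, group: str | None = None, replicate: str | None = None) -> "EventTable":
        df = self.data
        if group is not None:
            df = df[df["group"] == group]
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        return EventTable(df.reset_index(drop=True))


def normalize_status(value) -> int:
    """Map 0/1 or 'death'/'censored' (case-insensitive) to the integer code."""
    if isinstance(value, str):
        key = value.strip().lower()
        if key in _STATUS_STRINGS:
            return _STATUS_STRINGS[key]
        raise ValueError(
            f"unknown status {value!r}: use 1/'death' or 0/'censored' "
            "(live animals at assay end are censored at last observation)"
        )
    iv = int(value)
    if iv not in (DEATH, CENSORED):
        raise ValueError(f"status must be 0 or 1, got {value!r}")
    return iv


def kaplan_meier(
    events: EventTable,
    days: Sequence[float] | np.ndarray | None = None,
    label: str | None = None,
) -> SurvivalCurve:
    """Product-limit survival estimate, in percent of the starting count.

    Ŝ(t) = Π_{tᵢ<=t} (1 − dᵢ/nᵢ) over distinct death times; censored
    subjects leave the risk set after their censoring time, with deaths
    processed before censorings at tied times.

    Parameters
    ----------
    events
        The event table (one row per individual).
    days
        Optional evaluation grid, e.g. every scored day of a daily assay.
        By default the curve holds day 0 plus each distinct event day.
    """
    df = events.data
    if events.n_deaths == 0:
        warnings.warn("all-censored event table: survival is flat at 100%")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time_days"], event_observed=df["status"])
    if days is None:
        days = np.unique(np.concatenate(([0.0], df["time_days"].to_numpy())))
    days = np.asarray(days, dtype=float)
    surv = kmf.survival_function_at_times(days).to_numpy()
    return SurvivalCurve(days=days, percent=100.0 * surv, n0=events.n0, label=label)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        """True when p < 0.05, the conventional significance threshold."""
        return self.p_value < 0.05


def log_rank(events_a: EventTable, events_b: EventTable) -> LogRankResult:
    """Mantel–Cox comparison of two survival experiences.

    The statistic pools distinct death times across both groups, compares
    observed with expected deaths under the null, uses the hypergeometric
    variance, and is referred to the chi-square distribution with one degree
    of freedom.

    Raises
    ------
    ValueError
        If either table contains no deaths (test undefined).
    """
    if events_a.n_deaths == 0 or events_b.n_deaths == 0:
        raise ValueError("log-rank test undefined without deaths in both groups")
    res = logrank_test(
        events_a.data["time_days"],
        events_b.data["time_days"],
        event_observed_A=events_a.data["status"],
        event_observed_B=events_b.data["status"],
    )
    return LogRankResult(float(res.test_statistic), float(res.p_value))
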