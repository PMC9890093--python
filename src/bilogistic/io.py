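"""File I/O, run configuration and the end-to-end analysis pipeline.

Two CSV dialects are accepted, auto-detected by header:

* event tables — ``time_days,status,group,replicate`` with status ``1`` /
  ``death`` or ``0`` / ``censored`` (one row per individual);
* pre-aggregated curves — ``day,percent_surviving``.

Every file the pipeline writes starts with a provenance comment line
carrying the seed and a hash of the configuration, so a bundle can always
be traced back to (and reproduced from) its run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import compare_groups, summarize_replicates
from .fitting import FitResult, SurvivalCurve, fit_least_squares, fit_mle
from .models import MODEL_IDS
from .nonparametric import EventTable, kaplan_meier
from .selection import ALLOWED_BIN_WIDTHS, bin_residuals, compare_models

__all__ = [
    "RunConfig",
    "ReportBundle",
    "read_event_table",
    "write_event_table",
    "read_curve",
    "write_curve",
    "read_input",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_EVENT_COLS = ["time_days", "status", "group", "replicate"]
_CURVE_COLS = ["day", "percent_surviving"]


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_event_table(path: str | Path) -> EventTable:
    """Read and validate a per-individual event CSV.

    Malformed rows are reported with their line numbers (1-based, counting
    the header).
    """
    df = _read_csv(path)
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    offenders = []
    times = pd.to_numeric(df["time_days"], errors="coerce")
    for i in df.index[~np.isfinite(times) | (times < 0)]:
        offenders.append((int(i) + 2, f"bad time_days {df.loc[i, 'time_days']!r}"))
    from .nonparametric import normalize_status

    for i, s in df["status"].items():
        try:
            normalize_status(s)
        except ValueError as exc:
            offenders.append((int(i) + 2, str(exc)))
    if offenders:
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in offenders)
        raise ValueError(f"{path}: {lines}")
    return EventTable(df)


def write_event_table(events: EventTable, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        events.data[_EVENT_COLS].to_csv(fh, index=False)


def read_curve(path: str | Path, n0: int = 100) -> SurvivalCurve:
    """Read a pre-aggregated ``day,percent_surviving`` CSV."""
    df = _read_csv(path)
    missing = [c for c in _CURVE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return SurvivalCurve(
        days=df["day"].to_numpy(float),
        percent=df["percent_surviving"].to_numpy(float),
        n0=n0,
        label=Path(path).stem,
    )


def write_curve(curve: SurvivalCurve, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        curve.to_frame().to_csv(fh, index=False)


def read_input(path: str | Path) -> EventTable | SurvivalCurve:
    """Auto-detect the dialect by header and read accordingly."""
    head = pd.read_csv(path, comment="#", nrows=0)
    if set(_CURVE_COLS) <= set(head.columns):
        return read_curve(path)
    return read_event_table(path)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input_path: str
    models: Sequence[str]
    output_dir: str
    fit_method: str = "both"  # least-squares | mle | both
    bin_widths: Sequence[int] = (2, 3, 4)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must be non-empty")
        unknown = [m for m in self.models if m not in MODEL_IDS]
        if unknown:
            raise ValueError(f"unknown model id(s) {unknown}; choose from {MODEL_IDS}")
        bad = [w for w in self.bin_widths if w not in ALLOWED_BIN_WIDTHS]
        if bad:
            raise ValueError(f"bin widths {bad} unsupported; allowed: {ALLOWED_BIN_WIDTHS}")
        if self.fit_method not in ("least-squares", "mle", "both"):
            raise ValueError("fit_method must be least-squares, mle or both")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset handles JSON too
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """What a pipeline run produced and where."""

    output_dir: Path
    files: list[Path] = field(default_factory=list)
    n_fits: int = 0
    n_nonconverged: int = 0

    @property
    def exit_status(self) -> int:
        return 1 if self.n_nonconverged else 0


def _provenance(config: RunConfig) -> str:
    return f"bilogistic config_hash={config.config_hash()} seed={config.seed}"


def _write_df(df: pd.DataFrame, path: Path, config: RunConfig, bundle: ReportBundle) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_provenance(config)}\n")
        df.to_csv(fh, index=False)
    bundle.files.append(path)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full workflow on an event-table CSV.

    Per replicate: a Kaplan–Meier curve and a fit for every requested
    model.  Per group: AICc / adjusted-RMSE model comparison, residual-bin
    summaries for the requested widths, and a cohort summary for the first
    (primary) model.  With two or more eligible groups, a between-group
    ANOVA/Tukey table per parameter of the primary model.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=outdir)

    data = read_input(config.input_path)
    if isinstance(data, SurvivalCurve):
        groups = {"all": [("curve", None, data)]}
    else:
        groups = {}
        for (grp, rep), sub in data.data.groupby(["group", "replicate"], sort=True):
            ev = EventTable(sub.reset_index(drop=True))
            days = np.arange(0.0, float(ev.data["time_days"].max()) + 1.0)
            curve = kaplan_meier(ev, days=days, label=f"{grp}/{rep}")
            groups.setdefault(grp, []).append((rep, ev, curve))

    primary = config.models[0]
    fit_rows: list[dict] = []
    cohort_summaries = []
    for grp, entries in groups.items():
        curves = [c for _, _, c in entries]
        for (rep, _, curve) in entries:
            _write_df(
                curve.to_frame(),
                outdir / f"km_{grp}_{rep}.csv",
                config,
                bundle,
            )
        ls_fits: dict[str, list[FitResult]] = {m: [] for m in config.models}
        for rep, _, curve in entries:
            for model_id in config.models:
                for method, fitter in (
                    ("least-squares", fit_least_squares),
                    ("mle", fit_mle),
                ):
                    if config.fit_method not in (method, "both"):
                        continue
                    try:
                        fr = fitter(curve, model_id, seed=config.seed)
                    except Exception as exc:  # noqa: BLE001
                        logger.warning("fit failed: %s/%s %s: %s", grp, rep, model_id, exc)
                        continue
                    bundle.n_fits += 1
                    if not fr.converged:
                        bundle.n_nonconverged += 1
                    logger.info(
                        "%s/%s %s (%s): sse=%.4g aicc=%.4g converged=%s",
                        grp, rep, model_id, method, fr.sse, fr.aicc, fr.converged,
                    )
                    row = {"group": grp, "replicate": rep}
                    row.update(fr.to_dict())
                    fit_rows.append(row)
                    if method == "least-squares":
                        ls_fits[model_id].append(fr)

        comparison = compare_models(curves, config.models, seed=config.seed)
        _write_df(comparison.to_tidy(), outdir / f"comparison_{grp}.csv", config, bundle)
        _write_df(
            comparison.best_counts_frame(), outdir / f"best_counts_{grp}.csv", config, bundle
        )

        bin_frames = []
        for model_id in config.models:
            resids = [f.residuals for f in ls_fits[model_id]]
            if not resids:
                continue
            for w in config.bin_widths:
                summary = bin_residuals(resids, w)
                bf = summary.bins.copy()
                bf.insert(0, "width", w)
                bf.insert(0, "model", model_id)
                bin_frames.append(bf)
        if bin_frames:
            _write_df(
                pd.concat(bin_frames, ignore_index=True),
                outdir / f"residual_bins_{grp}.csv",
                config,
                bundle,
            )

        converged_primary = [f for f in ls_fits[primary] if f.converged]
        if converged_primary:
            cohort_summaries.append(summarize_replicates(converged_primary, group=grp))

    if fit_rows:
        _write_df(pd.DataFrame(fit_rows), outdir / "fits.csv", config, bundle)
    if cohort_summaries:
        summary_rows = []
        for s in cohort_summaries:
            for p in s.table.columns:
                summary_rows.append(
                    {"group": s.group, "model": s.model_id, "parameter": p,
                     "mean": s.means[p], "sem": s.sems[p], "n": s.n}
                )
        _write_df(pd.DataFrame(summary_rows), outdir / "cohort_summary.csv", config, bundle)
        eligible = [s for s in cohort_summaries if s.n >= 2]
        if len(eligible) >= 2:
            frames = [
                compare_groups(eligible, parameter=p).to_frame()
                for p in eligible[0].table.columns
            ]
            _write_df(
                pd.concat(frames, ignore_index=True),
                outdir / "anova_tukey.csv",
                config,
                bundle,
            )

    echo = asdict(config)
    echo["config_hash"] = config.config_hash()
    cfg_path = outdir / "config.json"
    cfg_path.write_text(json.dumps(echo, indent=2, default=list))
    bundle.files.append(cfg_path)
    return bundle
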