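"""Parameter estimation for lifespan curves.

Two routes are provided, mirroring common practice in lifespan analysis:

* :func:`fit_least_squares` — bounded nonlinear least squares with a
  trust-region algorithm, minimizing the sum of squared differences between
  observed and predicted percent survival.
* :func:`fit_mle` — maximum likelihood under independent Gaussian errors on
  the survival percentages with a common unknown scale σ.  σ is profiled
  out analytically (σ̂² = SSE/m, ln L = −m/2·[ln(2π σ̂²) + 1]), so the MLE
  point estimates of the shape parameters coincide with the least-squares
  estimates; the route exists to supply a log-likelihood for AIC/AICc.  The
  default polish optimizer is the derivative-free Nelder–Mead simplex,
  switched to bounded quasi-Newton (L-BFGS-B) for the Gompertz and
  Gompertz–Makeham models whose exponential-of-exponential form it handles
  better.

Parameter bounds are enforced by a smooth scaled-logit transform, so every
optimizer works in an unconstrained internal space.  All fits are
multi-start (a deterministic heuristic initialization plus seeded
perturbations) and fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .models import (
    N0,
    ModelSpec,
    ParameterSet,
    _predict,
    get_model,
    validate_params,
)
from .selection import adjusted_rmse, aicc

__all__ = [
    "SurvivalCurve",
    "FitResult",
    "DegenerateInputError",
    "initialize_params",
    "fit_least_squares",
    "fit_mle",
    "curve_from_model",
]

#: Profiled noise variance floor (σ >= 1e-8) so the log-likelihood stays
#: finite on noise-free curves.
_SIGMA2_FLOOR = 1e-16

_N_PERTURBED_STARTS = 8


class DegenerateInputError(ValueError):
    """Raised for curves that cannot identify the requested model."""


@dataclass
class SurvivalCurve:
    """A (day, percent-surviving) series with its starting count.

    Days are strictly increasing (first day >= 0) and percentages
    non-increasing, starting at or below 100.
    """

    days: np.ndarray
    percent: np.ndarray
    n0: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.percent.shape:
            raise ValueError("days and percent must be 1-d arrays of equal length")
        if self.days.size == 0:
            raise ValueError("empty survival curve")
        if self.days[0] < 0 or np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing and start at >= 0")
        if self.percent[0] > 100.0 + 1e-9:
            raise ValueError("percent surviving cannot exceed 100")
        if np.any(np.diff(self.percent) > 1e-9):
            raise ValueError("percent surviving must be non-increasing")

    def __len__(self) -> int:
        return self.days.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": self.days, "percent_surviving": self.percent}
        )


def curve_from_model(
    model_id: str,
    params: ParameterSet | Mapping[str, float],
    days: Sequence[float] | np.ndarray,
    n0: int = 100,
    label: str | None = None,
) -> SurvivalCurve:
    """Noise-free curve sampled from a model — handy for tests and demos."""
    from .models import evaluate_model

    days = np.asarray(days, dtype=float)
    return SurvivalCurve(days, evaluate_model(model_id, params, days), n0, label)


@dataclass
class FitResult:
    """Estimated parameters plus goodness-of-fit bookkeeping for one curve."""

    model_id: str
    params: ParameterSet
    sse: float
    loglik: float
    aic: float
    aicc: float
    rmse_adj: float
    residuals: list[tuple[float, float]]
    m: int
    n_params: int
    converged: bool
    method: str  # "least-squares" | "mle"
    seed: int

    def to_dict(self) -> dict:
        """Flat key-value report suitable for a JSON/CSV row."""
        out = {"model": self.model_id, "method": self.method}
        out.update({f"param_{k}": v for k, v in self.params.values.items()})
        out.update(
            sse=self.sse,
            loglik=self.loglik,
            aic=self.aic,
            aicc=self.aicc,
            rmse_adj=self.rmse_adj,
            m=self.m,
            n_params=self.n_params,
            converged=self.converged,
            seed=self.seed,
        )
        return out


# ----------------------------------------------------------------- transforms

def _to_internal(spec: ModelSpec, values: Mapping[str, float]) -> np.ndarray:
    x = np.empty(spec.n_params)
    for i, name in enumerate(spec.param_names):
        lo, hi = spec.bounds[name]
        r = (values[name] - lo) / (hi - lo)
        x[i] = logit(np.clip(r, 1e-12, 1.0 - 1e-12))
    return x


def _from_internal(spec: ModelSpec, x: np.ndarray) -> dict[str, float]:
    v = {}
    for i, name in enumerate(spec.param_names):
        lo, hi = spec.bounds[name]
        v[name] = float(lo + (hi - lo) * expit(x[i]))
    return v


# ------------------------------------------------------------- initialization

def _first_crossing(days: np.ndarray, percent: np.ndarray, q: float) -> float | None:
    idx = np.nonzero(percent <= q)[0]
    return float(days[idx[0]]) if idx.size else None


def initialize_params(curve: SurvivalCurve, model_id: str) -> ParameterSet:
    """Deterministic heuristic start values inside the model's bounds.

    Time parameters come from the days where the curve first crosses 75%,
    50% and 25% survival (with a span-based fallback when a quantile is
    never reached); rates from the steepest observed per-day decline divided
    by 25, since a logistic phase declines at k·N0/4 ≈ 25k %/day at its
    midpoint; the phase weight starts at 0.5.
    """
    spec = get_model(model_id)
    days, pct = curve.days, curve.percent
    if len(curve) < spec.n_params + 2:
        raise DegenerateInputError(
            f"curve with {len(curve)} points cannot initialize {model_id} "
            f"({spec.n_params} parameters)"
        )
    span = float(days[-1] - days[0])
    if span <= 0 or float(pct[0] - pct[-1]) <= 0:
        raise DegenerateInputError("constant curve: no decline to fit")

    lo_d = float(days[0])
    t75 = _first_crossing(days, pct, 75.0)
    t50 = _first_crossing(days, pct, 50.0)
    t25 = _first_crossing(days, pct, 25.0)
    t1 = t75 if t75 is not None else lo_d + 0.25 * span
    t2 = t25 if t25 is not None else lo_d + 0.75 * span
    tmed = t50 if t50 is not None else 0.5 * (t1 + t2)
    if t2 <= t1:
        t2 = t1 + max(0.5, 0.1 * span)
    tmed = max(tmed, 0.2)
    t1 = max(t1, 0.2)

    decline = float(np.max(-np.diff(pct) / np.diff(days)))  # %/day, > 0 here
    def _clip(v: float, name: str) -> float:
        lo, hi = spec.bounds[name]
        return float(np.clip(v, lo * (1 + 1e-6) if name != "f" else lo, hi))

    k0 = decline / 25.0
    if model_id == "bilogistic-1kf":
        raw = {"f": 0.5, "k": k0, "t1": t1, "t2": t2}
    elif model_id == "bilogistic-2kf":
        raw = {"f": 0.5, "k1": k0, "k2": k0, "t1": t1, "t2": t2}
    elif model_id == "bilogistic-2k":
        raw = {"k1": k0, "k2": k0, "t1": t1, "t2": t2}
    elif model_id == "whiting-buchanan":
        raw = {"f": 0.5, "k1": k0, "k2": k0, "tlag": tmed}
    elif model_id == "logistic":
        raw = {"tlag": tmed, "logistic_scale": 25.0 / decline}
    elif model_id == "wilson":
        # Wilson slope at the median is k·N0/(4·tlag) %/day.
        raw = {"tlag": tmed, "k": decline * 4.0 * tmed / N0}
    elif model_id == "weibull":
        b0 = 2.0
        raw = {"a": math.log(2.0) ** (1.0 / b0) / tmed, "b": b0}
    elif model_id in ("gompertz", "gompertz-makeham"):
        b0 = 0.1
        a0 = b0 * math.log(2.0) / math.expm1(b0 * tmed)
        raw = {"a": a0, "b": b0}
        if model_id == "gompertz-makeham":
            raw["c"] = 1e-3
    else:  # pragma: no cover - catalogue is closed
        raise ValueError(model_id)
    return validate_params(model_id, {k: _clip(v, k) for k, v in raw.items()})


# --------------------------------------------------------------------- fitting

def _sse_fun(spec: ModelSpec, days: np.ndarray, pct: np.ndarray):
    def residual(x: np.ndarray) -> np.ndarray:
        return pct - _predict(spec.model_id, _from_internal(spec, x), days)

    def sse(x: np.ndarray) -> float:
        r = residual(x)
        return float(r @ r)

    return residual, sse


def _starts(spec: ModelSpec, x0: np.ndarray, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    pts = [x0]
    # perturbations are uniform in the internal (scaled-logit) space, i.e.
    # roughly log-uniform multiplicative jitter for rates and times
    for _ in range(_N_PERTURBED_STARTS):
        pts.append(x0 + rng.uniform(-0.8, 0.8, size=x0.size))
    return pts


def _finalize(
    curve: SurvivalCurve,
    spec: ModelSpec,
    values: Mapping[str, float],
    converged: bool,
    method: str,
    seed: int,
) -> FitResult:
    pset = validate_params(spec.model_id, values)
    pred = _predict(spec.model_id, pset.values, curve.days)
    resid = curve.percent - pred
    m = len(curve)
    sse = float(resid @ resid)
    sigma2 = max(sse / m, _SIGMA2_FLOOR)
    loglik = -0.5 * m * (math.log(2.0 * math.pi * sigma2) + 1.0)
    aic = 2.0 * spec.n_params - 2.0 * loglik
    aicc_val = aicc(aic, spec.n_params, m) if m > spec.n_params + 1 else math.nan
    return FitResult(
        model_id=spec.model_id,
        params=pset,
        sse=sse,
        loglik=loglik,
        aic=aic,
        aicc=aicc_val,
        rmse_adj=adjusted_rmse(resid, spec.n_params),
        residuals=list(zip(curve.days.tolist(), resid.tolist())),
        m=m,
        n_params=spec.n_params,
        converged=converged,
        method=method,
        seed=seed,
    )


def fit_least_squares(
    curve: SurvivalCurve,
    model_id: str,
    init: ParameterSet | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit a model by bounded trust-region nonlinear least squares.

    Multi-start: the heuristic initialization plus eight seeded
    perturbations; the lowest-SSE solution wins.  The result is
    canonicalized (``t1 <= t2``) and its SSE is never worse than at the
    initialization point.
    """
    spec = get_model(model_id)
    if len(curve) <= spec.n_params:
        raise DegenerateInputError(
            f"{len(curve)} points cannot fit {model_id} ({spec.n_params} parameters)"
        )
    if init is None:
        init = initialize_params(curve, model_id)
    residual, sse = _sse_fun(spec, curve.days, curve.percent)
    x0 = _to_internal(spec, init.values)
    best_x, best_sse, converged = x0, sse(x0), False
    for start in _starts(spec, x0, seed):
        try:
            res = optimize.least_squares(
                residual, start, method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=4000,
            )
        except Exception:  # noqa: BLE001 - a bad start must not kill the fit
            continue
        s = sse(res.x)
        if s < best_sse:
            best_x, best_sse = res.x, s
        converged = converged or bool(res.success)
    return _finalize(
        curve, spec, _from_internal(spec, best_x), converged, "least-squares", seed
    )


#: Models polished with bounded quasi-Newton instead of Nelder–Mead.
_QUASI_NEWTON_MODELS = ("gompertz", "gompertz-makeham")


def fit_mle(
    curve: SurvivalCurve,
    model_id: str,
    init: ParameterSet | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit a model by maximum likelihood (Gaussian errors, σ profiled out).

    Because the profiled Gaussian log-likelihood is a monotone transform of
    the SSE, the shape-parameter estimates coincide with the least-squares
    estimates; the least-squares solution therefore serves as one of the
    starts and is polished with a simplex (or quasi-Newton for the Gompertz
    family) search on the likelihood surface.
    """
    spec = get_model(model_id)
    if len(curve) <= spec.n_params + 1:
        raise DegenerateInputError(
            f"{len(curve)} points cannot support MLE/AICc for {model_id} "
            f"({spec.n_params} parameters)"
        )
    ls = fit_least_squares(curve, model_id, init=init, seed=seed)
    _, sse = _sse_fun(spec, curve.days, curve.percent)
    x0 = _to_internal(spec, ls.params.values)
    if not np.isfinite(sse(x0)):  # fall back to the heuristic start
        x0 = _to_internal(spec, initialize_params(curve, model_id).values)
    method = "L-BFGS-B" if model_id in _QUASI_NEWTON_MODELS else "Nelder-Mead"
    opts = (
        {"maxiter": 2000}
        if method == "L-BFGS-B"
        else {"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000}
    )
    best_x, best_sse = x0, sse(x0)
    try:
        res = optimize.minimize(sse, x0, method=method, options=opts)
        if np.isfinite(res.fun) and res.fun <= best_sse:
            best_x, best_sse = res.x, float(res.fun)
    except Exception:  # noqa: BLE001 - keep the least-squares solution
        pass
    return _finalize(
        curve, spec, _from_internal(spec, best_x), ls.converged, "mle", seed
    )
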