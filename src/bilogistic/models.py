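"""Parametric survival models for lifespan assays.

The bilogistic family describes biphasic survival curves as a two-component
mixture of logistic survival terms: a fraction ``f`` of the population is
short-lived with median survival ``t1``, the remaining ``1 - f`` long-lived
with median ``t2``.  The numerator factor ``1 + exp(-k * t_i)`` in each term
rescales the phase so the curve starts exactly at ``N0`` (fixed at 100%) at
day 0.  The family has three members:

* ``bilogistic-1kf`` — one shared death rate ``k``, free weight ``f`` (4 params)
* ``bilogistic-2kf`` — two death rates ``k1``, ``k2``, free ``f`` (5 params)
* ``bilogistic-2k``  — two death rates, ``f`` fixed at 0.5 (4 params)

The 2kf model contains the other two as limit cases (``k1 == k2`` and
``f == 0.5`` respectively) and generalizes the Whiting–Buchanan model, which
uses a single time constant ``tlag`` for both phases.  Six classical
comparator models (Whiting–Buchanan, Gompertz–Makeham, Logistic, Wilson,
Weibull, Gompertz) are included for model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "N0",
    "MODEL_IDS",
    "ModelSpec",
    "ParameterSet",
    "InvalidModelError",
    "ValidationError",
    "ReductionError",
    "get_model",
    "validate_params",
    "evaluate_model",
    "reduce_model",
]

#: Starting population, rescaled to percent. Fixed, never fitted.
N0 = 100.0


class InvalidModelError(ValueError):
    """Raised for a model identifier outside the nine-model catalogue."""


class ValidationError(ValueError):
    """Raised when a parameter value violates its bounds or is missing."""


class ReductionError(ValueError):
    """Raised when a limit-case reduction's condition is not met."""


# Default bounds: a generous envelope for worm/fly assays.
_RATE = (1e-4, 10.0)          # death rates, day^-1
_TIME = (0.1, 200.0)          # median survival / lag times, days
_FRACTION = (0.0, 1.0)        # phase weight, inclusive
_EXPONENT = (1e-2, 100.0)     # dimensionless steepness (Wilson k, Weibull b)
_MAKEHAM = (1e-6, 10.0)       # age-independent mortality term


@dataclass(frozen=True)
class ModelSpec:
    """Identifier, ordered parameter symbols and per-parameter bounds."""

    model_id: str
    param_names: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _spec(model_id: str, **bounds: tuple[float, float]) -> ModelSpec:
    return ModelSpec(model_id, tuple(bounds), dict(bounds))


_CATALOGUE: dict[str, ModelSpec] = {
    s.model_id: s
    for s in (
        _spec("bilogistic-1kf", f=_FRACTION, k=_RATE, t1=_TIME, t2=_TIME),
        _spec("bilogistic-2kf", f=_FRACTION, k1=_RATE, k2=_RATE, t1=_TIME, t2=_TIME),
        _spec("bilogistic-2k", k1=_RATE, k2=_RATE, t1=_TIME, t2=_TIME),
        _spec("whiting-buchanan", f=_FRACTION, k1=_RATE, k2=_RATE, tlag=_TIME),
        _spec("gompertz-makeham", a=_RATE, b=_RATE, c=_MAKEHAM),
        # eq. (2.6)'s denominator symbol is a time scale, not a death rate;
        # stored as logistic_scale to avoid collision with the bilogistic k.
        _spec("logistic", tlag=_TIME, logistic_scale=_TIME),
        _spec("wilson", tlag=_TIME, k=_EXPONENT),
        _spec("weibull", a=_RATE, b=_EXPONENT),
        _spec("gompertz", a=_RATE, b=_RATE),
    )
}

MODEL_IDS: tuple[str, ...] = tuple(_CATALOGUE)

#: Models whose survival equals N0 exactly at t = 0 (the Logistic does not).
STARTS_AT_N0: tuple[str, ...] = tuple(m for m in MODEL_IDS if m != "logistic")


def get_model(model_id: str) -> ModelSpec:
    try:
        return _CATALOGUE[model_id]
    except KeyError:
        raise InvalidModelError(
            f"unknown model {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


@dataclass(frozen=True)
class ParameterSet:
    """A validated, canonicalized point in a model's parameter space."""

    model_id: str
    values: Mapping[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def _canonicalize(model_id: str, v: dict[str, float]) -> dict[str, float]:
    # Phase labels are interchangeable; fix t1 <= t2 so fitted parameters
    # are comparable across replicates.
    if model_id in ("bilogistic-1kf", "bilogistic-2kf") and v["t1"] > v["t2"]:
        v["t1"], v["t2"] = v["t2"], v["t1"]
        v["f"] = 1.0 - v["f"]
        if model_id == "bilogistic-2kf":
            v["k1"], v["k2"] = v["k2"], v["k1"]
    elif model_id == "bilogistic-2k" and v["t1"] > v["t2"]:
        v["t1"], v["t2"] = v["t2"], v["t1"]
        v["k1"], v["k2"] = v["k2"], v["k1"]
    return v


def validate_params(model_id: str, raw: Mapping[str, float]) -> ParameterSet:
    """Validate raw values against the model's bounds and canonicalize.

    For the biphasic models the phase labels are swapped if needed so that
    ``t1 <= t2`` (with ``f -> 1 - f``), which leaves the curve unchanged.

    Raises
    ------
    ValidationError
        On a missing symbol, non-finite value, or out-of-bounds value.
    """
    spec = get_model(model_id)
    missing = [p for p in spec.param_names if p not in raw]
    if missing:
        raise ValidationError(f"{model_id}: missing parameter(s) {missing}")
    v: dict[str, float] = {}
    for name in spec.param_names:
        x = float(raw[name])
        if not math.isfinite(x):
            raise ValidationError(f"{model_id}: parameter {name} is not finite")
        lo, hi = spec.bounds[name]
        ok = (lo <= x <= hi) if name == "f" else (lo < x <= hi)
        if not ok:
            raise ValidationError(
                f"{model_id}: parameter {name}={x:g} outside bounds ({lo:g}, {hi:g}]"
            )
        v[name] = x
    return ParameterSet(model_id, _canonicalize(model_id, v))


def _logistic_phase(t: np.ndarray, k: float, tmed: float) -> np.ndarray:
    # (1 + e^{-k tmed}) / (1 + e^{k (t - tmed)}) in log space so the term
    # stays finite for k*t up to ~700 and beyond.
    return np.exp(np.logaddexp(0.0, -k * tmed) - np.logaddexp(0.0, k * (t - tmed)))


def _predict(model_id: str, v: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    """Evaluate a model's survival formula without validation (hot path)."""
    if model_id == "bilogistic-1kf":
        f, k = v["f"], v["k"]
        return N0 * (
            f * _logistic_phase(t, k, v["t1"])
            + (1.0 - f) * _logistic_phase(t, k, v["t2"])
        )
    if model_id == "bilogistic-2kf":
        f = v["f"]
        return N0 * (
            f * _logistic_phase(t, v["k1"], v["t1"])
            + (1.0 - f) * _logistic_phase(t, v["k2"], v["t2"])
        )
    if model_id == "bilogistic-2k":
        return 0.5 * N0 * (
            _logistic_phase(t, v["k1"], v["t1"])
            + _logistic_phase(t, v["k2"], v["t2"])
        )
    if model_id == "whiting-buchanan":
        f, tlag = v["f"], v["tlag"]
        return N0 * (
            f * _logistic_phase(t, v["k1"], tlag)
            + (1.0 - f) * _logistic_phase(t, v["k2"], tlag)
        )
    if model_id == "gompertz-makeham":
        a, b, c = v["a"], v["b"], v["c"]
        return N0 * np.exp(-c * t - (a / b) * np.expm1(np.minimum(b * t, 700.0)))
    if model_id == "logistic":
        z = (t - v["tlag"]) / v["logistic_scale"]
        return N0 * np.exp(-np.logaddexp(0.0, z))
    if model_id == "wilson":
        with np.errstate(divide="ignore"):
            return N0 / (1.0 + (t / v["tlag"]) ** v["k"])
    if model_id == "weibull":
        return N0 * np.exp(-((v["a"] * t) ** v["b"]))
    if model_id == "gompertz":
        a, b = v["a"], v["b"]
        return N0 * np.exp(-(a / b) * np.expm1(np.minimum(b * t, 700.0)))
    raise InvalidModelError(f"unknown model {model_id!r}")


def evaluate_model(
    model_id: str,
    params: ParameterSet | Mapping[str, float],
    times: Iterable[float] | np.ndarray,
) -> np.ndarray:
    """Evaluate a model's survival curve N(t) in percent at given days.

    Parameters
    ----------
    model_id
        One of the nine catalogue identifiers.
    params
        A :class:`ParameterSet` for the model, or a raw mapping which is
        validated first.
    times
        Day values, all >= 0.

    Returns
    -------
    numpy.ndarray
        Percent surviving at each time; finite for all valid inputs, equal
        to ``N0`` (= 100) at t = 0 for every model except the Logistic.
    """
    if isinstance(params, ParameterSet):
        if params.model_id != model_id:
            raise ValidationError(
                f"parameter set is for {params.model_id!r}, not {model_id!r}"
            )
        pset = validate_params(model_id, params.values)
    else:
        pset = validate_params(model_id, params)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    return _predict(model_id, pset.values, t)


_REDUCTIONS = ("bilogistic-1kf", "bilogistic-2k", "whiting-buchanan")


def reduce_model(
    params_2kf: ParameterSet,
    target: str,
    tol: float = 1e-9,
) -> ParameterSet:
    """Reduce a Bilogistic 2kf parameter set to one of its limit cases.

    The 2kf model collapses to 1kf when ``k1 == k2``, to 2k when ``f == 0.5``
    and to Whiting–Buchanan when ``t1 == t2``; in each case the reduced
    model's curve equals the 2kf curve at every time point.

    Raises
    ------
    ReductionError
        If the relevant limit condition is violated beyond ``tol``
        (relative, for rates and times).
    """
    if params_2kf.model_id != "bilogistic-2kf":
        raise InvalidModelError("reduce_model expects a bilogistic-2kf parameter set")
    if target not in _REDUCTIONS:
        raise InvalidModelError(
            f"cannot reduce to {target!r}; expected one of {_REDUCTIONS}"
        )
    v = params_2kf.values
    if target == "bilogistic-1kf":
        if abs(v["k1"] - v["k2"]) > tol * max(abs(v["k1"]), abs(v["k2"])):
            raise ReductionError(
                f"k1 != k2 ({v['k1']:g} vs {v['k2']:g}); 1kf limit requires equal rates"
            )
        return validate_params(
            target, {"f": v["f"], "k": v["k1"], "t1": v["t1"], "t2": v["t2"]}
        )
    if target == "bilogistic-2k":
        if abs(v["f"] - 0.5) > tol:
            raise ReductionError(
                f"f = {v['f']:g} != 0.5; 2k limit requires equal phase weighting"
            )
        return validate_params(
            target, {"k1": v["k1"], "k2": v["k2"], "t1": v["t1"], "t2": v["t2"]}
        )
    # whiting-buchanan
    if abs(v["t1"] - v["t2"]) > tol * max(abs(v["t1"]), abs(v["t2"])):
        raise ReductionError(
            f"t1 != t2 ({v['t1']:g} vs {v['t2']:g}); "
            "Whiting–Buchanan limit requires a single time constant"
        )
    return validate_params(
        target, {"f": v["f"], "k1": v["k1"], "k2": v["k2"], "tlag": v["t1"]}
    )
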