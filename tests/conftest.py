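"""Shared fixtures: simulated replicate sets and independent fit oracles.

The heavy session fixtures mirror a realistic daily-scored nematode assay:
15 replicates of 100 individuals each, biphasic truth
1kf(f=0.6, k=0.4 /day, t1=12 d, t2=22 d) — well inside the range reported
for wild-type worms — plus a monophasic control set (f=1, single logistic
phase).  Seeds are fixed so every run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import bilogistic as bl

BIPHASIC_SEED = 20230991
MONOPHASIC_SEED = 40220991
BIPHASIC_TRUTH = dict(f=0.6, k=0.4, t1=12.0, t2=22.0)
MONOPHASIC_TRUTH = dict(f=1.0, k=0.4, t1=17.0, t2=30.0)  # phase 2 unused


@pytest.fixture(scope="session")
def truth_1kf() -> bl.ParameterSet:
    return bl.validate_params("bilogistic-1kf", BIPHASIC_TRUTH)


@pytest.fixture(scope="session")
def biphasic_replicates(truth_1kf):
    """15 replicates x 100 individuals from the biphasic truth."""
    cfg = bl.SimulationConfig(
        truth=truth_1kf, n_individuals=100, n_replicates=15, seed=BIPHASIC_SEED
    )
    return bl.make_replicate_set(cfg)


@pytest.fixture(scope="session")
def biphasic_fits_1kf(biphasic_replicates):
    """Per-replicate maximum-likelihood 1kf fits of the biphasic set."""
    return [
        bl.fit_mle(curve, "bilogistic-1kf") for _, curve in biphasic_replicates
    ]


@pytest.fixture(scope="session")
def monophasic_replicates():
    """15 replicates whose truth is a single logistic phase (f = 1)."""
    truth = bl.validate_params("bilogistic-1kf", MONOPHASIC_TRUTH)
    cfg = bl.SimulationConfig(
        truth=truth, n_individuals=100, n_replicates=15, seed=MONOPHASIC_SEED
    )
    return bl.make_replicate_set(cfg)


# --------------------------------------------------------- independent oracles
# Closed-form survival formulas written out directly (independent of the
# package's evaluation path) and a brute-force SSE grid search over them.

def _oracle_logistic(t, tlag, scale):
    with np.errstate(over="ignore"):
        return 100.0 / (1.0 + np.exp(np.minimum((t - tlag) / scale, 700.0)))


def _oracle_wilson(t, tlag, k):
    with np.errstate(over="ignore", divide="ignore"):
        return 100.0 / (1.0 + (t / tlag) ** k)


def _oracle_weibull(t, a, b):
    return 100.0 * np.exp(-((a * t) ** b))


def _oracle_gompertz(t, a, b):
    with np.errstate(over="ignore"):
        return 100.0 * np.exp(-(a / b) * (np.exp(np.minimum(b * t, 700.0)) - 1.0))


#: model id -> (oracle fn, (axis-1 grid, axis-2 grid)) for 2-parameter models
TWO_PARAM_ORACLES = {
    "logistic": (_oracle_logistic,
                 (np.geomspace(1.0, 60.0, 200), np.geomspace(0.2, 30.0, 200))),
    "wilson": (_oracle_wilson,
               (np.geomspace(1.0, 60.0, 200), np.geomspace(0.5, 60.0, 200))),
    "weibull": (_oracle_weibull,
                (np.geomspace(0.005, 1.0, 200), np.geomspace(0.5, 15.0, 200))),
    "gompertz": (_oracle_gompertz,
                 (np.geomspace(1e-4, 0.5, 200), np.geomspace(1e-3, 1.0, 200))),
}


def brute_force_sse(model_id: str, curve) -> float:
    """Minimum SSE over a 200x200 parameter lattice, via the oracle formulas."""
    fn, (g1, g2) = TWO_PARAM_ORACLES[model_id]
    p1, p2 = np.meshgrid(g1, g2, indexing="ij")
    pred = fn(curve.days[None, None, :], p1[..., None], p2[..., None])
    sse = np.sum((curve.percent[None, None, :] - pred) ** 2, axis=-1)
    return float(sse.min())
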