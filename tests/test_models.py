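"""The nine survival formulas, their invariants and limit-case relations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bilogistic as bl
from bilogistic.models import STARTS_AT_N0, _predict

GRID = np.linspace(0.0, 60.0, 600)


def _random_params(rng, model_id):
    """A random valid parameter set well inside each model's bounds."""
    draws = {
        "f": rng.uniform(0.0, 1.0),
        "k": rng.uniform(0.05, 3.0),
        "k1": rng.uniform(0.05, 3.0),
        "k2": rng.uniform(0.05, 3.0),
        "t1": rng.uniform(1.0, 60.0),
        "t2": rng.uniform(1.0, 60.0),
        "tlag": rng.uniform(1.0, 60.0),
        "logistic_scale": rng.uniform(0.5, 20.0),
        "a": rng.uniform(1e-3, 0.5),
        "b": rng.uniform(1e-3, 0.8),
        "c": rng.uniform(1e-5, 0.05),
    }
    if model_id == "wilson":
        draws["k"] = rng.uniform(0.5, 20.0)
    if model_id == "weibull":
        draws["a"] = rng.uniform(0.01, 0.5)
        draws["b"] = rng.uniform(0.5, 8.0)
    names = bl.get_model(model_id).param_names
    return bl.validate_params(model_id, {n: draws[n] for n in names})


class TestEvaluate:
    def test_hand_value_1kf_at_midphase(self):
        """1kf(f=0.5, k=1, t1=10, t2=20) at t=10 matches hand arithmetic."""
        p = dict(f=0.5, k=1.0, t1=10.0, t2=20.0)
        expected = 100.0 * (
            0.5 * (1 + np.exp(-10)) / 2 + 0.5 * (1 + np.exp(-20)) / (1 + np.exp(-10))
        )
        got = bl.evaluate_model("bilogistic-1kf", p, [10.0])[0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(75.0, abs=2e-3)

    def test_starts_at_n0(self):
        """Every model except the Logistic returns exactly N0 at t=0."""
        rng = np.random.default_rng(11)
        for model_id in STARTS_AT_N0:
            for _ in range(25):
                p = _random_params(rng, model_id)
                assert bl.evaluate_model(model_id, p, [0.0])[0] == pytest.approx(
                    100.0, abs=1e-9
                )

    def test_logistic_is_half_n0_at_tlag(self):
        got = bl.evaluate_model("logistic", dict(tlag=15, logistic_scale=2), [15.0])
        assert got[0] == pytest.approx(50.0, abs=1e-12)

    def test_unknown_model_and_bad_params(self):
        with pytest.raises(bl.InvalidModelError):
            bl.evaluate_model("bilogistic-3k", dict(k=1), [0.0])
        with pytest.raises(bl.ValidationError, match="f"):
            bl.evaluate_model("bilogistic-1kf", dict(f=1.2, k=1, t1=5, t2=10), [0.0])
        with pytest.raises(bl.ValidationError):
            bl.evaluate_model("gompertz", dict(a=0.1, b=0.1), [-1.0])

    def test_overflow_guard(self):
        """Curves stay finite even when k*t reaches 700."""
        p = dict(f=0.5, k=10.0, t1=10.0, t2=70.0)
        vals = bl.evaluate_model("bilogistic-1kf", p, [0.0, 35.0, 70.0, 200.0])
        assert np.all(np.isfinite(vals))

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        for model_id in bl.MODEL_IDS:
            for _ in range(10):
                p = _random_params(rng, model_id)
                vals = bl.evaluate_model(model_id, p, GRID)
                assert np.all(np.diff(vals) <= 1e-9), model_id


class TestValidate:
    def test_canonical_swap_1kf(self):
        p = bl.validate_params("bilogistic-1kf", dict(f=0.3, k=1, t1=20, t2=10))
        assert p.values == dict(f=0.7, k=1.0, t1=10.0, t2=20.0)

    def test_already_canonical_2k_unchanged(self):
        p = bl.validate_params("bilogistic-2k", dict(k1=0.3, k2=0.8, t1=5, t2=25))
        assert p.values == dict(k1=0.3, k2=0.8, t1=5.0, t2=25.0)

    def test_missing_and_nan(self):
        with pytest.raises(bl.ValidationError, match="missing"):
            bl.validate_params("bilogistic-1kf", dict(f=0.5, k=1, t1=10))
        with pytest.raises(bl.ValidationError, match="finite"):
            bl.validate_params("gompertz", dict(a=np.nan, b=0.1))

    @given(
        f=st.floats(0.0, 1.0),
        k=st.floats(0.05, 3.0),
        t1=st.floats(1.0, 60.0),
        t2=st.floats(1.0, 60.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_swap_symmetry(self, f, k, t1, t2):
        """Exchanging phase labels (t1<->t2, f<->1-f) leaves N(t) unchanged."""
        a = _predict("bilogistic-1kf", dict(f=f, k=k, t1=t1, t2=t2), GRID)
        b = _predict("bilogistic-1kf", dict(f=1 - f, k=k, t1=t2, t2=t1), GRID)
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-9)

    def test_swap_symmetry_2kf(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            f, k1, k2 = rng.uniform(0, 1), rng.uniform(0.05, 3), rng.uniform(0.05, 3)
            t1, t2 = rng.uniform(1, 60, 2)
            a = _predict("bilogistic-2kf", dict(f=f, k1=k1, k2=k2, t1=t1, t2=t2), GRID)
            b = _predict("bilogistic-2kf", dict(f=1 - f, k1=k2, k2=k1, t1=t2, t2=t1), GRID)
            np.testing.assert_allclose(a, b, rtol=0, atol=1e-9)


class TestReduce:
    def test_equal_rates_reduce_to_1kf(self):
        p = bl.validate_params(
            "bilogistic-2kf", dict(f=0.3, k1=0.4, k2=0.4, t1=8, t2=20)
        )
        r = bl.reduce_model(p, "bilogistic-1kf")
        assert r.values == dict(f=0.3, k=0.4, t1=8.0, t2=20.0)
        a = bl.evaluate_model("bilogistic-2kf", p, GRID)
        b = bl.evaluate_model("bilogistic-1kf", r, GRID)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_half_weight_reduces_to_2k(self):
        p = bl.validate_params(
            "bilogistic-2kf", dict(f=0.5, k1=0.3, k2=0.8, t1=8, t2=20)
        )
        r = bl.reduce_model(p, "bilogistic-2k")
        a = bl.evaluate_model("bilogistic-2kf", p, GRID)
        b = bl.evaluate_model("bilogistic-2k", r, GRID)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_equal_times_reduce_to_whiting_buchanan(self):
        p = bl.validate_params(
            "bilogistic-2kf", dict(f=0.4, k1=0.3, k2=0.9, t1=12, t2=12)
        )
        r = bl.reduce_model(p, "whiting-buchanan")
        assert r.values["tlag"] == 12.0
        a = bl.evaluate_model("bilogistic-2kf", p, GRID)
        b = bl.evaluate_model("whiting-buchanan", r, GRID)
        assert np.max(np.abs(a - b)) == 0.0

    def test_limit_equivalence_random(self):
        """Limit-case identities hold to <1e-12 relative on a 600-pt grid."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            k, t1, t2 = rng.uniform(0.05, 3), *sorted(rng.uniform(1, 60, 2))
            f = rng.uniform(0, 1)
            p = bl.validate_params(
                "bilogistic-2kf", dict(f=f, k1=k, k2=k, t1=t1, t2=t2)
            )
            r = bl.reduce_model(p, "bilogistic-1kf")
            a = bl.evaluate_model("bilogistic-2kf", p, GRID)
            b = bl.evaluate_model("bilogistic-1kf", r, GRID)
            assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-300)) < 1e-12

    def test_violated_condition_raises(self):
        p = bl.validate_params(
            "bilogistic-2kf", dict(f=0.3, k1=0.3, k2=0.8, t1=8, t2=20)
        )
        with pytest.raises(bl.ReductionError, match="k1"):
            bl.reduce_model(p, "bilogistic-1kf")
        with pytest.raises(bl.ReductionError, match="f"):
            bl.reduce_model(p, "bilogistic-2k")
        with pytest.raises(bl.ReductionError, match="t1"):
            bl.reduce_model(p, "whiting-buchanan")
        with pytest.raises(bl.InvalidModelError):
            bl.reduce_model(p, "weibull")

    def test_single_phase_collapse(self):
        """1kf with t1 = t2 = T equals a single normalized logistic phase."""
        T, k = 14.0, 0.6
        p = dict(f=0.37, k=k, t1=T, t2=T)
        got = bl.evaluate_model("bilogistic-1kf", p, GRID)
        expected = 100.0 * (1 + np.exp(-k * T)) / (1 + np.exp(k * (GRID - T)))
        np.testing.assert_allclose(got, expected, rtol=1e-12)
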