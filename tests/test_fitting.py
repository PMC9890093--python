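"""Least-squares and maximum-likelihood estimation on survival curves."""

import numpy as np
import pytest

import bilogistic as bl
from conftest import TWO_PARAM_ORACLES, brute_force_sse

DAYS_41 = np.arange(0.0, 41.0)


@pytest.fixture(scope="module")
def clean_1kf_curve():
    p = bl.validate_params("bilogistic-1kf", dict(f=0.6, k=0.4, t1=12, t2=22))
    return bl.curve_from_model("bilogistic-1kf", p, DAYS_41)


class TestSurvivalCurve:
    def test_rejects_increasing_percent(self):
        with pytest.raises(ValueError):
            bl.SurvivalCurve(days=[0, 1, 2], percent=[100, 60, 70], n0=100)

    def test_rejects_unsorted_days(self):
        with pytest.raises(ValueError):
            bl.SurvivalCurve(days=[0, 2, 1], percent=[100, 90, 80], n0=100)


class TestInitialize:
    def test_quantile_heuristic_brackets_truth(self, clean_1kf_curve):
        init = bl.initialize_params(clean_1kf_curve, "bilogistic-1kf")
        assert 8.0 <= init["t1"] <= 12.0
        assert 18.0 <= init["t2"] <= 22.0
        assert init["f"] == 0.5

    def test_shallow_curve_uses_fallback(self):
        # never falls below 75%: quantile rule falls back to span fractions
        days = np.arange(0.0, 20.0)
        pct = 100.0 - 0.5 * days
        curve = bl.SurvivalCurve(days, pct, n0=100)
        init = bl.initialize_params(curve, "bilogistic-1kf")
        assert init["t1"] < init["t2"]

    def test_too_few_points_refused(self):
        curve = bl.SurvivalCurve([0.0, 10.0], [100.0, 50.0], n0=100)
        with pytest.raises(bl.DegenerateInputError):
            bl.initialize_params(curve, "bilogistic-1kf")

    def test_constant_curve_refused(self):
        curve = bl.SurvivalCurve(np.arange(10.0), np.full(10, 100.0), n0=100)
        with pytest.raises(bl.DegenerateInputError):
            bl.initialize_params(curve, "bilogistic-1kf")


class TestLeastSquares:
    def test_noise_free_recovery(self, clean_1kf_curve):
        fr = bl.fit_least_squares(clean_1kf_curve, "bilogistic-1kf")
        assert fr.converged
        assert fr.params["f"] == pytest.approx(0.6, abs=1e-4)
        assert fr.params["k"] == pytest.approx(0.4, abs=1e-4)
        assert fr.params["t1"] == pytest.approx(12.0, abs=1e-4)
        assert fr.params["t2"] == pytest.approx(22.0, abs=1e-4)

    def test_noise_free_logistic_exact(self):
        curve = bl.curve_from_model(
            "logistic", dict(tlag=15, logistic_scale=2.5), DAYS_41
        )
        fr = bl.fit_least_squares(curve, "logistic")
        assert fr.sse < 1e-10

    def test_recovery_across_random_truths(self):
        """Noise-free 1kf curves return their parameters to 4 decimals."""
        rng = np.random.default_rng(77)
        for _ in range(50):
            truth = dict(
                f=rng.uniform(0.2, 0.8),
                k=rng.uniform(0.3, 2.0),
                t1=rng.uniform(5.0, 15.0),
            )
            truth["t2"] = truth["t1"] + rng.uniform(8.0, 25.0)
            curve = bl.curve_from_model("bilogistic-1kf", truth, np.arange(0.0, 61.0))
            fr = bl.fit_least_squares(curve, "bilogistic-1kf")
            for name, val in truth.items():
                assert fr.params[name] == pytest.approx(val, abs=1e-4), name

    def test_fit_refused_below_dof(self):
        curve = bl.SurvivalCurve([0.0, 5, 10, 15], [100, 80, 40, 10], n0=100)
        with pytest.raises(bl.DegenerateInputError):
            bl.fit_least_squares(curve, "bilogistic-1kf")

    def test_result_bookkeeping(self, clean_1kf_curve):
        fr = bl.fit_least_squares(clean_1kf_curve, "bilogistic-1kf")
        assert fr.m == len(clean_1kf_curve)
        assert len(fr.residuals) == fr.m
        sse = sum(r * r for _, r in fr.residuals)
        assert fr.sse == pytest.approx(sse, abs=1e-9)
        assert fr.aicc >= fr.aic
        d = fr.to_dict()
        assert d["model"] == "bilogistic-1kf" and "param_t1" in d

    def test_determinism(self, biphasic_replicates):
        curve = biphasic_replicates[0][1]
        a = bl.fit_least_squares(curve, "bilogistic-1kf", seed=3)
        b = bl.fit_least_squares(curve, "bilogistic-1kf", seed=3)
        assert a.params.values == b.params.values
        assert a.sse == b.sse

    def test_beats_two_param_grid_oracle(self, biphasic_replicates):
        curve = biphasic_replicates[1][1]
        for model_id in TWO_PARAM_ORACLES:
            fr = bl.fit_least_squares(curve, model_id)
            assert fr.sse <= brute_force_sse(model_id, curve) + 1e-9, model_id


class TestMLE:
    @pytest.mark.parametrize(
        "model_id",
        ["bilogistic-1kf", "bilogistic-2k", "whiting-buchanan",
         "logistic", "wilson", "weibull", "gompertz", "gompertz-makeham"],
    )
    def test_mle_matches_least_squares(self, model_id, biphasic_replicates):
        """Gaussian MLE point estimates coincide with least squares."""
        curve = biphasic_replicates[2][1]
        ls = bl.fit_least_squares(curve, model_id)
        mle = bl.fit_mle(curve, model_id)
        assert abs(mle.sse - ls.sse) / max(ls.sse, 1e-12) < 1e-6

    def test_noise_free_loglik_finite(self, clean_1kf_curve):
        fr = bl.fit_mle(clean_1kf_curve, "bilogistic-1kf")
        assert np.isfinite(fr.loglik) and fr.sse < 1e-12

    def test_biphasic_data_favours_1kf_over_logistic(self, biphasic_replicates):
        curve = biphasic_replicates[0][1]
        ll_1kf = bl.fit_mle(curve, "bilogistic-1kf").loglik
        ll_log = bl.fit_mle(curve, "logistic").loglik
        assert ll_1kf > ll_log

    def test_aic_definition(self, biphasic_replicates):
        fr = bl.fit_mle(biphasic_replicates[0][1], "bilogistic-1kf")
        assert fr.aic == pytest.approx(2 * fr.n_params - 2 * fr.loglik, rel=1e-12)

    def test_requires_extra_point(self):
        curve = bl.SurvivalCurve(
            [0.0, 5, 10, 15, 20], [100, 80, 60, 30, 10], n0=100
        )
        with pytest.raises(bl.DegenerateInputError):
            bl.fit_mle(curve, "bilogistic-1kf")
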