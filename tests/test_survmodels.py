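import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from hetsurv import (
    CoxPHModel,
    DGMConfig,
    ExponentialPHModel,
    ModelSpec,
    StepBaseline,
    breslow_baseline,
    fit_cox,
    fit_exponential_ph,
    generate_cohort,
    km_survival,
    load_model,
    oe_ratio,
    predict_survival,
    recalibrate_baseline,
    save_model,
)
from oracles import exponential_rate_mle_by_group


def _binary_cohort(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 2, size=n)
    rate = 0.1 * np.exp(math.log(2) * g)
    t = rng.exponential(1.0 / rate)
    return pd.DataFrame(
        {"subject_id": np.arange(n), "g": g, "observed_time": t, "event": 1}
    )


class TestExponentialFit:
    def test_matches_closed_form_group_mle(self):
        # single binary covariate, no censoring: beta-hat has a closed form
        c = _binary_cohort()
        model = fit_exponential_ph(c, ["g"])
        oracle = exponential_rate_mle_by_group(c["observed_time"], c["event"], c["g"])
        assert model.coefficients[0] == pytest.approx(oracle, abs=1e-6)

    def test_recovers_generating_hazard_ratio(self, nocens_cohort):
        model = fit_exponential_ph(nocens_cohort, ["x"])
        assert math.exp(model.coefficients[0]) == pytest.approx(2.0, rel=0.03)
        assert float(model.baseline) == pytest.approx(0.1, rel=0.03)

    def test_null_predictor_recovered_as_zero(self):
        c = generate_cohort(DGMConfig(n=100_000, log_hazard_ratio=0.0, seed=31))
        model = fit_exponential_ph(c, ["x"])
        assert abs(model.coefficients[0]) < 0.02

    def test_degenerate_data_rejected(self):
        c = _binary_cohort(50)
        c["event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_exponential_ph(c, ["g"])


class TestCoxFit:
    def test_recovers_generating_hazard_ratio(self, cox_model):
        assert math.exp(cox_model.coefficients[0]) == pytest.approx(2.0, rel=0.03)
        assert cox_model.baseline_kind == "step_function"

    def test_agrees_with_exponential_fit(self, admin_cohort, cox_model):
        exp_model = fit_exponential_ph(admin_cohort, ["x"])
        # both consistent for the same generating mechanism
        assert cox_model.coefficients[0] == pytest.approx(
            exp_model.coefficients[0], abs=0.02
        )

    def test_constant_predictor_rejected(self):
        c = _binary_cohort(100)
        c["flat"] = 1.0
        with pytest.raises(ValueError, match="variation"):
            fit_cox(c, ["flat"])

    def test_missing_column_rejected(self, nocens_cohort):
        with pytest.raises(KeyError):
            fit_cox(nocens_cohort, ["nonexistent"])


class TestPrediction:
    def test_exponential_closed_form(self):
        model = ModelSpec(("x",), np.array([math.log(2)]), "exponential_rate", 0.1)
        s = model.predict_survival(pd.DataFrame({"x": [1.0]}), 6.5)
        assert s[0] == pytest.approx(math.exp(-1.3), abs=1e-12)

    def test_zero_lp_returns_baseline(self):
        base = StepBaseline(np.array([1.0, 2.0]), np.array([0.8, 0.5]), t_max=3.0)
        model = ModelSpec(("x",), np.array([0.7]), "step_function", base)
        s = model.predict_survival(pd.DataFrame({"x": [0.0]}), 1.5)
        assert s[0] == 0.8

    def test_monotone_in_predictor(self, cox_model):
        x = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
        s = cox_model.predict_survival(x, 6.5)
        assert np.all(np.diff(s) < 0)
        assert np.all((s >= 0) & (s <= 1))

    def test_cox_and_exponential_agree_on_exponential_data(
        self, admin_cohort, cox_model
    ):
        exp_model = fit_exponential_ph(admin_cohort, ["x"])
        s_cox = cox_model.predict_survival(admin_cohort, 6.5)
        s_exp = exp_model.predict_survival(admin_cohort, 6.5)
        assert np.max(np.abs(s_cox - s_exp)) < 0.01

    def test_in_sample_mean_calibration(self, admin_cohort, cox_model):
        s = cox_model.predict_survival(admin_cohort, 6.5)
        s_km = km_survival(admin_cohort["observed_time"], admin_cohort["event"], 6.5)
        assert s.mean() == pytest.approx(s_km, abs=0.005)

    def test_extrapolation_fails_then_clamps(self, cox_model):
        x = pd.DataFrame({"x": [0.0]})
        t_max = cox_model.baseline.t_max
        with pytest.raises(ValueError, match="extrapolation"):
            cox_model.predict_survival(x, t_max + 1)
        s = cox_model.predict_survival(x, t_max + 1, extrapolation="clamp")
        assert 0 <= s[0] <= 1

    def test_prediction_table_wrapper(self, cox_model, admin_cohort):
        tbl = predict_survival(cox_model, admin_cohort.head(10), 6.5)
        assert list(tbl.columns) == ["subject_id", "predicted_survival", "horizon"]
        assert (tbl["horizon"] == 6.5).all()


class TestStepBaseline:
    def test_right_continuity_and_prior_value(self):
        base = StepBaseline(np.array([1.0, 3.0]), np.array([0.9, 0.4]), t_max=5.0)
        assert base(0.5) == 1.0
        assert base(1.0) == 0.9  # value at the step itself
        assert base(2.999) == 0.9
        assert base(3.0) == 0.4

    def test_rejects_increasing_survival(self):
        with pytest.raises(ValueError):
            StepBaseline(np.array([1.0, 2.0]), np.array([0.5, 0.8]), t_max=3.0)

    def test_null_offset_breslow_close_to_km(self, admin_cohort):
        times = admin_cohort["observed_time"].to_numpy()
        events = admin_cohort["event"].to_numpy()
        base = breslow_baseline(times, events, np.zeros(len(times)))
        for t in (2.0, 6.5, 12.0):
            assert base(t) == pytest.approx(km_survival(times, events, t), abs=0.005)


class TestRecalibration:
    def test_baseline_miscalibration_is_repaired(self, admin_cohort):
        fitted = fit_exponential_ph(admin_cohort, ["x"])
        bad = ModelSpec(
            ("x",), fitted.coefficients, "exponential_rate", float(fitted.baseline) * 3
        )
        t = admin_cohort["observed_time"].to_numpy()
        e = admin_cohort["event"].to_numpy()
        assert oe_ratio(bad.predict_survival(admin_cohort, 6.5), t, e, 6.5) < 0.8
        rec = recalibrate_baseline(bad, admin_cohort)
        assert rec.baseline_kind == "step_function"
        np.testing.assert_array_equal(rec.coefficients, bad.coefficients)
        oe = oe_ratio(rec.predict_survival(admin_cohort, 6.5), t, e, 6.5)
        assert oe == pytest.approx(1.0, abs=0.02)

    def test_idempotent_on_calibrated_model(self, admin_cohort, cox_model):
        rec = recalibrate_baseline(cox_model, admin_cohort)
        t = admin_cohort["observed_time"].to_numpy()
        e = admin_cohort["event"].to_numpy()
        oe = oe_ratio(rec.predict_survival(admin_cohort, 6.5), t, e, 6.5)
        assert oe == pytest.approx(1.0, abs=0.02)

    def test_null_lp_baseline_equals_marginal_survival(self, admin_cohort):
        null = ModelSpec(("x",), np.array([0.0]), "exponential_rate", 0.1)
        rec = recalibrate_baseline(null, admin_cohort)
        times = admin_cohort["observed_time"].to_numpy()
        events = admin_cohort["event"].to_numpy()
        for t in (2.0, 6.5, 12.0):
            assert rec.baseline(t) == pytest.approx(
                km_survival(times, events, t), abs=0.005
            )

    def test_requires_events(self, admin_cohort, cox_model):
        censored = admin_cohort.assign(event=0)
        with pytest.raises(ValueError):
            recalibrate_baseline(cox_model, censored)


class TestEstimators:
    def test_cox_estimator_matches_functional_fit(self, admin_cohort):
        est = CoxPHModel()
        X = admin_cohort[["x"]]
        y = (admin_cohort["observed_time"].to_numpy(), admin_cohort["event"].to_numpy())
        est.fit(X, y)
        spec = fit_cox(admin_cohort, ["x"])
        assert est.coef_[0] == pytest.approx(spec.coefficients[0], abs=1e-10)
        s_est = est.predict_survival(X.head(5), 6.5)
        s_spec = spec.predict_survival(admin_cohort.head(5), 6.5)
        np.testing.assert_allclose(s_est, s_spec)

    def test_exponential_estimator_attributes_and_clone(self, nocens_cohort):
        est = ExponentialPHModel(center=False)
        assert clone(est).get_params() == est.get_params()
        y = (
            nocens_cohort["observed_time"].to_numpy(),
            nocens_cohort["event"].to_numpy(),
        )
        est.fit(nocens_cohort[["x"]], y)
        assert est.rate_ == pytest.approx(0.1, rel=0.05)
        assert est.predict(nocens_cohort[["x"]].head(3)).shape == (3,)

    def test_structured_array_labels_accepted(self, nocens_cohort):
        y = np.empty(len(nocens_cohort), dtype=[("event", bool), ("time", float)])
        y["event"] = nocens_cohort["event"] == 1
        y["time"] = nocens_cohort["observed_time"]
        est = ExponentialPHModel().fit(nocens_cohort[["x"]], y)
        assert math.exp(est.coef_[0]) == pytest.approx(2.0, rel=0.05)


class TestSerialization:
    def test_yaml_round_trip_preserves_predictions(self, tmp_path, cox_model, admin_cohort):
        path = tmp_path / "model.yaml"
        save_model(cox_model, path)
        back = load_model(path)
        np.testing.assert_allclose(
            back.predict_survival(admin_cohort.head(20), 6.5),
            cox_model.predict_survival(admin_cohort.head(20), 6.5),
        )

    def test_external_model_from_published_coefficients(self):
        # a model representable without refitting
        spec = ModelSpec(
            ("age", "bmi"),
            np.array([0.03, 0.12]),
            "exponential_rate",
            0.002,
            centering_offsets=np.array([45.0, 24.0]),
        )
        df = pd.DataFrame({"age": [45.0], "bmi": [24.0]})
        assert spec.predict_survival(df, 6.0)[0] == pytest.approx(
            math.exp(-0.002 * 6.0)
        )
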