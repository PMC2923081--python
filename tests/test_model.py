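"""Logistic expression model: prediction, IWLS fit, significance, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from pgpscan import (
    AxisProfile,
    ExpressionModel,
    coefficient_significance,
    cross_validate,
    fit_model,
    goodness_of_fit,
    knockdown,
    predict_expression,
)
from pgpscan.model import (
    _conc_frame,
    _design,
    _validate_spec,
    bernoulli_loglik,
    default_covariate_spec,
    sigmoid,
)
from pgpscan.simulate import simulate_training_data


def lbfgs_oracle(X, y, ridge):
    """Independent optimizer for the same ridge-penalized Bernoulli
    objective the IWLS fit maximizes."""

    def negobj(b):
        return -(bernoulli_loglik(y, sigmoid(X @ b)) - 0.5 * ridge * b @ b)

    def grad(b):
        mu = sigmoid(X @ b)
        return -(X.T @ (y - mu) - ridge * b)

    res = minimize(
        negobj, np.zeros(X.shape[1]), jac=grad, method="L-BFGS-B",
        options={"maxiter": 20000, "ftol": 1e-17, "gtol": 1e-12},
    )
    return -res.fun


def _design_for(data):
    return _design(
        data.S, _conc_frame(data.concentrations),
        _validate_spec(data.covariate_spec),
    )


class TestPredict:
    def test_zero_weights_give_half_everywhere(self):
        model = ExpressionModel(
            tf_weights={"A": 0.0}, baselines={"c": 0.0},
            covariate_spec=[{"tf": "A", "order": 1}],
        )
        conc = pd.DataFrame({"A": np.linspace(0, 1, 100)}).T
        prof = predict_expression(model, "c", {"A": 2.0}, conc)
        np.testing.assert_allclose(prof.values, 0.5)

    def test_closed_form_single_term(self):
        model = ExpressionModel(
            tf_weights={"A": 1.0}, baselines={"c": -1.0},
            covariate_spec=[{"tf": "A", "order": 1}],
        )
        conc = pd.DataFrame({"A": np.full(100, 2.0)}).T
        prof = predict_expression(model, "c", {"A": 1.0}, conc)
        np.testing.assert_allclose(prof.values, 1 / (1 + np.exp(-1)), atol=1e-9)

    def test_repressor_suppresses_only_its_domain(self):
        c_rep = np.zeros(100)
        c_rep[39:60] = 1.0
        conc = pd.DataFrame({"A": np.full(100, 1.0), "R": c_rep}).T
        spec = default_covariate_spec(["A", "R"])
        base = ExpressionModel({"A": 1.0, "R": 0.0}, {"c": 0.0}, spec)
        with_r = ExpressionModel({"A": 1.0, "R": -5.0}, {"c": 0.0}, spec)
        p0 = predict_expression(base, "c", {"A": 1.0, "R": 2.0}, conc).values
        p1 = predict_expression(with_r, "c", {"A": 1.0, "R": 2.0}, conc).values
        assert np.all(p1[39:60] < p0[39:60])
        np.testing.assert_allclose(p1[:39], p0[:39])
        np.testing.assert_allclose(p1[60:], p0[60:])

    def test_missing_tf_named_in_error(self):
        model = ExpressionModel(
            tf_weights={"A": 1.0}, baselines={"c": 0.0},
            covariate_spec=[{"tf": "A", "order": 1}],
        )
        conc = pd.DataFrame({"A": np.full(100, 1.0)}).T
        with pytest.raises(KeyError, match="A"):
            predict_expression(model, "c", {}, conc)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(8)
        conc = pd.DataFrame(
            {"A": rng.random(100), "B": rng.random(100)}
        ).T
        spec = default_covariate_spec(["A", "B"], squared=["A"])
        model = ExpressionModel(
            {"A": 1.3, "B": -0.7, "A^2": 0.2}, {"c": 0.4}, spec
        )
        s = {"A": 1.7, "B": 0.9}
        got = predict_expression(model, "c", s, conc).values
        covA = conc.loc["A"].to_numpy() * s["A"]
        covB = conc.loc["B"].to_numpy() * s["B"]
        eta = 0.4 + 1.3 * covA - 0.7 * covB + 0.2 * covA**2
        np.testing.assert_allclose(got, 1 / (1 + np.exp(-eta)), atol=1e-12)


class TestFit:
    def test_sign_recovery_and_scaled_weights_noise_free(self, training_data,
                                                         fitted_model):
        model, _ = fitted_model
        w_true = np.array(
            [training_data.weights[tf] for tf in training_data.S.columns]
        )
        w_fit = np.array(
            [model.tf_weights[tf] for tf in training_data.S.columns]
        )
        assert np.all(np.sign(w_fit) == np.sign(w_true))
        scale = (w_fit @ w_true) / (w_true @ w_true)
        assert np.max(np.abs(w_fit / scale - w_true) / np.abs(w_true)) < 0.10

    def test_activator_repressor_split_reproduced(self, training_data,
                                                  fitted_model):
        model, _ = fitted_model
        for tf in training_data.S.columns:
            expected_positive = tf in training_data.activators
            assert (model.tf_weights[tf] > 0) == expected_positive

    def test_iwls_matches_independent_optimizer(self, training_data,
                                                fitted_model):
        model, report = fitted_model
        X, crms, names = _design_for(training_data)
        y = training_data.targets_clean.to_numpy().ravel()
        beta = np.array(
            [model.baselines[c] for c in crms]
            + [model.tf_weights[n] for n in names]
        )
        obj_iwls = bernoulli_loglik(y, sigmoid(X @ beta)) \
            - 0.5 * model.ridge * beta @ beta
        obj_oracle = lbfgs_oracle(X, y, model.ridge)
        assert abs(obj_iwls - obj_oracle) <= 1e-6

    def test_single_crm_constant_target_absorbed_by_baseline(self):
        conc = pd.DataFrame({"A": np.linspace(0, 1, 100)}).T
        S = pd.DataFrame({"A": [1.0]}, index=["c"])
        targets = pd.DataFrame([np.ones(100)], index=["c"])
        model, _ = fit_model(S, conc, targets)
        assert model.separation_flagged
        assert model.baselines["c"] > 1.0

    def test_zero_variance_covariate_dropped(self):
        conc = pd.DataFrame(
            {"A": np.linspace(0, 1, 100), "Z": np.zeros(100)}
        ).T
        rng = np.random.default_rng(0)
        S = pd.DataFrame(
            {"A": rng.random(4) + 0.5, "Z": rng.random(4)},
            index=list("abcd"),
        )
        targets = pd.DataFrame(
            (rng.random((4, 100)) < 0.5).astype(float), index=list("abcd")
        )
        with pytest.warns(UserWarning, match="Z"):
            model, _ = fit_model(S, conc, targets)
        assert model.tf_weights["Z"] == 0.0
        assert "Z" in model.dropped_terms

    def test_non_binary_targets_rejected(self):
        conc = pd.DataFrame({"A": np.linspace(0, 1, 100)}).T
        S = pd.DataFrame({"A": [1.0, 2.0]}, index=["a", "b"])
        targets = pd.DataFrame(np.full((2, 100), 0.3), index=["a", "b"])
        with pytest.raises(ValueError):
            fit_model(S, conc, targets)

    def test_order2_term_never_hurts_loglik(self, noisy_training_data):
        data = noisy_training_data
        spec1 = data.covariate_spec
        spec2 = spec1 + [{"tf": "BCDx", "order": 2}]
        _, r1 = fit_model(data.S, data.concentrations, data.targets_noisy, spec1)
        _, r2 = fit_model(data.S, data.concentrations, data.targets_noisy, spec2)
        assert r2.loglik >= r1.loglik - 1e-6

    def test_order2_requires_order1(self):
        conc = pd.DataFrame({"A": np.linspace(0, 1, 100)}).T
        S = pd.DataFrame({"A": [1.0, 2.0]}, index=["a", "b"])
        targets = pd.DataFrame(
            np.zeros((2, 100)), index=["a", "b"]
        )
        with pytest.raises(ValueError):
            fit_model(S, conc, targets, covariate_spec=[{"tf": "A", "order": 2}])

    def test_serialization_round_trip(self, fitted_model):
        model, _ = fitted_model
        back = ExpressionModel.from_json(model.to_json())
        assert back.tf_weights == model.tf_weights
        assert back.baselines == model.baselines


class TestSignificance:
    def test_zero_weight_zero_z(self):
        model = ExpressionModel(
            {"A": 0.0}, {"c": 0.0}, [{"tf": "A", "order": 1}],
            standard_errors={"A": 0.5},
        )
        sig = coefficient_significance(model)
        assert sig.loc["A", "z"] == 0.0
        assert sig.loc["A", "p"] == pytest.approx(1.0)

    def test_normal_quantile(self):
        model = ExpressionModel(
            {"A": 1.96}, {"c": 0.0}, [{"tf": "A", "order": 1}],
            standard_errors={"A": 1.0},
        )
        assert coefficient_significance(model).loc["A", "p"] == pytest.approx(
            0.05, abs=1e-3
        )

    def test_zero_se_reported_undefined(self):
        model = ExpressionModel(
            {"A": 1.0}, {"c": 0.0}, [{"tf": "A", "order": 1}],
            standard_errors={"A": 0.0},
        )
        assert np.isnan(coefficient_significance(model).loc["A", "p"])

    def test_z_grows_with_sample_size(self):
        zs = {}
        for n_crms in (10, 40):
            data = simulate_training_data(seed=21, n_crms=n_crms, noise=0.1)
            model, _ = fit_model(
                data.S, data.concentrations, data.targets_noisy,
                data.covariate_spec,
            )
            sig = coefficient_significance(model)
            zs[n_crms] = np.abs(sig["z"]).median()
        assert zs[40] > zs[10]


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        spec = [{"tf": "A", "order": 1}]
        conc = pd.DataFrame({"A": np.concatenate([np.ones(50), np.zeros(50)])}).T
        # huge weight: prediction saturates to the target pattern
        model = ExpressionModel({"A": 1000.0}, {"c": -500.0}, spec)
        S = pd.DataFrame({"A": [1.0]}, index=["c"])
        targets = pd.DataFrame(
            [np.concatenate([np.ones(50), np.zeros(50)])], index=["c"]
        )
        rep = goodness_of_fit(model, S, conc, targets)
        assert rep.rmse == pytest.approx(0.0, abs=1e-6)
        assert rep.mean_cc == pytest.approx(1.0, abs=1e-6)

    def test_constant_half_prediction_rmse(self):
        spec = [{"tf": "A", "order": 1}]
        conc = pd.DataFrame({"A": np.zeros(100)}).T
        model = ExpressionModel({"A": 1.0}, {"c": 0.0}, spec)
        S = pd.DataFrame({"A": [1.0]}, index=["c"])
        rng = np.random.default_rng(0)
        targets = pd.DataFrame(
            [(rng.random(100) < 0.5).astype(float)], index=["c"]
        )
        rep = goodness_of_fit(model, S, conc, targets)
        assert rep.rmse == pytest.approx(0.5)
        assert rep.n_cc_excluded == 1  # constant prediction excluded from CC

    def test_aic_matches_direct_likelihood_summation(self, training_data,
                                                     fitted_model):
        model, report = fitted_model
        conc = training_data.concentrations
        ll = 0.0
        for crm in training_data.S.index:
            mu = predict_expression(
                model, crm, training_data.S.loc[crm].to_dict(), conc
            ).values
            y = training_data.targets_clean.loc[crm].to_numpy()
            for b in range(100):
                ll += y[b] * np.log(mu[b]) + (1 - y[b]) * np.log(1 - mu[b])
        k = len(model.covariate_spec) + len(model.baselines)
        assert report.aic == pytest.approx(2 * k - 2 * ll, abs=1e-6)


class TestCrossValidate:
    def test_deterministic_under_seed(self, noisy_training_data):
        d = noisy_training_data
        a = cross_validate(d.S, d.concentrations, d.targets_noisy,
                           d.covariate_spec, reps=5, seed=42)
        b = cross_validate(d.S, d.concentrations, d.targets_noisy,
                           d.covariate_spec, reps=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_real_signal_beats_shuffled(self, noisy_training_data):
        d = noisy_training_data
        real = cross_validate(d.S, d.concentrations, d.targets_noisy,
                              d.covariate_spec, reps=30, seed=5)
        shuf = cross_validate(d.S, d.concentrations, d.targets_noisy,
                              d.covariate_spec, reps=30, seed=5, shuffle=True)
        p = mannwhitneyu(shuf, real, alternative="greater").pvalue
        assert np.median(shuf) > np.median(real)
        assert p < 0.01

    def test_pure_noise_targets_overlap(self):
        hits = 0
        for s in range(10):
            data = simulate_training_data(seed=300 + s, n_crms=12)
            rng = np.random.default_rng(600 + s)
            noise_targets = pd.DataFrame(
                (rng.random((12, 100)) < 0.5).astype(float),
                index=data.S.index, columns=data.targets_clean.columns,
            )
            real = cross_validate(data.S, data.concentrations, noise_targets,
                                  data.covariate_spec, reps=20, seed=s)
            shuf = cross_validate(data.S, data.concentrations, noise_targets,
                                  data.covariate_spec, reps=20, seed=s,
                                  shuffle=True)
            if mannwhitneyu(shuf, real, alternative="greater").pvalue > 0.05:
                hits += 1
        assert hits >= 8

    def test_reps_must_be_positive(self, noisy_training_data):
        d = noisy_training_data
        with pytest.raises(ValueError):
            cross_validate(d.S, d.concentrations, d.targets_noisy, reps=0)


class TestKnockdown:
    def _setup(self):
        spec = default_covariate_spec(["A", "R"])
        c_rep = np.zeros(100)
        c_rep[39:60] = 1.0
        conc = pd.DataFrame({"A": np.full(100, 0.8), "R": c_rep}).T
        return spec, conc

    def test_zero_weight_tf_no_effect(self):
        spec, conc = self._setup()
        model = ExpressionModel({"A": 1.0, "R": 0.0}, {"c": -0.5}, spec)
        s = {"A": 1.0, "R": 3.0}
        wt = predict_expression(model, "c", s, conc).values
        kd = knockdown(model, "R", "c", s, conc).values
        np.testing.assert_allclose(wt, kd)

    def test_repressor_knockdown_raises_activity_in_its_domain(self):
        spec, conc = self._setup()
        model = ExpressionModel({"A": 1.0, "R": -4.0}, {"c": -0.5}, spec)
        s = {"A": 1.0, "R": 3.0}
        wt = predict_expression(model, "c", s, conc).values
        kd = knockdown(model, "R", "c", s, conc).values
        assert np.all(kd[39:60] > wt[39:60])
        np.testing.assert_allclose(kd[:39], wt[:39])

    def test_sole_activator_knockdown_never_increases(self):
        spec, conc = self._setup()
        model = ExpressionModel({"A": 2.0, "R": -1.0}, {"c": 0.3}, spec)
        s = {"A": 1.5, "R": 1.0}
        wt = predict_expression(model, "c", s, conc).values
        kd = knockdown(model, "A", "c", s, conc).values
        assert np.all(kd <= wt + 1e-12)

    def test_unknown_tf_errors(self):
        spec, conc = self._setup()
        model = ExpressionModel({"A": 1.0, "R": -1.0}, {"c": 0.0}, spec)
        with pytest.raises(KeyError):
            knockdown(model, "X", "c", {"A": 1.0, "R": 1.0}, conc)
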