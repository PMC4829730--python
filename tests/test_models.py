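"""Model families: OLS core, PRESS shortcut, forward selection, benchmarks."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uema.models import (
    DegenerateFitError,
    InsufficientDataError,
    cap,
    fit_history_model,
    fit_mean_model,
    fit_ols,
    forward_select_aic,
    forward_select_cv,
    gaussian_aic,
    press_cv_mse,
)


def brute_force_loocv_mse(X: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: refit n times, each time predicting the left-out row."""
    n = len(y)
    if X.ndim == 1:
        X = X[:, None]
    errors = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        A = np.column_stack([np.ones(mask.sum()), X[mask]])
        beta, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
        errors[i] = y[i] - (np.concatenate([[1.0], X[i]]) @ beta)
    return float(np.mean(errors**2))


class TestOLS:
    def test_exact_linear_relation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_ols(x, 2 * x + 1)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.coef[0] == pytest.approx(2.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_constant_target_no_predictors(self):
        fit = fit_ols(np.empty((3, 0)), np.array([4.0, 4.0, 4.0]))
        assert fit.intercept == 4.0
        assert fit.sse == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, p = int(rng.integers(6, 25)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = fit_ols(X, y)
            A = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose([fit.intercept, *fit.coef], beta, atol=1e-8)
            H = A @ np.linalg.solve(A.T @ A, A.T)
            assert np.allclose(fit.leverages, np.diag(H), atol=1e-8)

    def test_rank_deficiency_names_column(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(DegenerateFitError, match="'b'"):
            fit_ols(X, np.array([1.0, 2.0, 1.0, 2.0]))


class TestPress:
    def test_two_point_closed_form(self):
        fit = fit_ols(np.empty((2, 0)), np.array([0.0, 3.0]))
        # LOO predictions are (3, 0): PRESS = 9 + 9 = 18, cv_mse = 9
        assert press_cv_mse(fit) == pytest.approx(9.0)

    def test_three_point_closed_form(self):
        fit = fit_ols(np.empty((3, 0)), np.array([1.0, 2.0, 3.0]))
        assert press_cv_mse(fit) == pytest.approx(1.5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equals_brute_force_refits(self, seed):
        """PRESS from a single fit == explicit n-refit LOOCV, to 1e-8."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        p = int(rng.integers(0, min(6, n - 2) + 1))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        fit = fit_ols(X, y)
        assert press_cv_mse(fit) == pytest.approx(
            brute_force_loocv_mse(X, y), abs=1e-8
        )


class TestCap:
    @pytest.mark.parametrize(
        "n, expected", [(42, 8), (20, 4), (23, 4), (5, 1), (4, 0)]
    )
    def test_floor_division_by_five(self, n, expected):
        assert cap(n) == expected


def _signal_instance(seed, n=40, p_noise=10, beta=2.0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 1 + p_noise))
    y = beta * X[:, 0] + rng.normal(0, noise, size=n)
    names = ["signal"] + [f"noise_{i}" for i in range(p_noise)]
    return pd.DataFrame(X, columns=names), y


class TestForwardSelectCV:
    def test_trace_strictly_decreasing(self):
        X, y = _signal_instance(0)
        model = forward_select_cv(X, y)
        vals = model.trace.values()
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_signal_variable_found_first(self):
        hits = 0
        for seed in range(20):
            X, y = _signal_instance(seed)
            model = forward_select_cv(X, y)
            hits += model.trace.variables[0] == "signal"
        assert hits >= 18
        # and residual error is of the order of the injected noise
        X, y = _signal_instance(3)
        model = forward_select_cv(X, y)
        assert model.trace.steps[-1].criterion < 3 * 0.1**2 + 0.05

    def test_each_step_matches_brute_force_loocv(self):
        """Accepted-step cv_mse equals a from-scratch refit-per-fold LOOCV."""
        X, y = _signal_instance(7, n=25, p_noise=6)
        model = forward_select_cv(X, y)
        chosen: list[str] = []
        for step in model.trace.steps:
            chosen.append(step.variable)
            oracle = brute_force_loocv_mse(X[chosen].to_numpy(), y)
            assert step.criterion == pytest.approx(oracle, abs=1e-8)

    def test_cap_respected(self):
        X, y = _signal_instance(1, n=20, p_noise=30)
        model = forward_select_cv(X, y)
        assert len(model.coefficients) <= cap(20)

    def test_pure_noise_selects_few_and_never_increases(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(40, 12)),
                         columns=[f"n{i}" for i in range(12)])
        y = rng.normal(size=40)
        model = forward_select_cv(X, y)
        vals = model.trace.values()
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_collinear_candidates_skipped_not_fatal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "dup": x, "b": rng.normal(size=30)})
        y = x + rng.normal(0, 0.1, size=30)
        model = forward_select_cv(X, y)
        assert "a" in model.coefficients
        assert "dup" not in model.coefficients


class TestForwardSelectAIC:
    def test_perfect_predictor_first(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            {"exact": np.arange(12.0), "junk": rng.normal(size=12)}
        )
        y = 3.0 * X["exact"].to_numpy() - 1.0
        model = forward_select_aic(X, y)
        assert model.trace.variables[0] == "exact"

    def test_aic_values_match_direct_formula(self):
        """Trace AICs equal n ln(SSE/n) + 2(k+2) with SSE from a plain refit."""
        X, y = _signal_instance(9, n=30, p_noise=5, noise=0.5)
        model = forward_select_aic(X, y)
        n = len(y)
        chosen: list[str] = []
        for k, step in enumerate(model.trace.steps, start=1):
            chosen.append(step.variable)
            A = np.column_stack([np.ones(n), X[chosen].to_numpy()])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = float(np.sum((y - A @ beta) ** 2))
            assert step.criterion == pytest.approx(
                n * np.log(sse / n) + 2 * (k + 2), abs=1e-8
            )

    def test_trace_strictly_decreasing_and_capped(self):
        X, y = _signal_instance(6, n=35, p_noise=20, noise=1.5)
        model = forward_select_aic(X, y)
        vals = model.trace.values()
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert len(model.coefficients) <= cap(35)


class TestBenchmarks:
    def test_mean_model(self):
        model = fit_mean_model([1.0, 2.0, 3.0])
        assert model.intercept == 2.0
        assert model.coefficients == {}

    def test_mean_model_loo_prediction_is_mean_of_others(self):
        y = np.array([1.0, 5.0, 6.0, 8.0])
        for i in range(4):
            others = np.delete(y, i)
            assert fit_mean_model(others).intercept == pytest.approx(others.mean())

    def test_history_model_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {"mood_lag1": rng.normal(size=15), "mood_lag2": rng.normal(size=15)}
        )
        y = rng.normal(size=15)
        model = fit_history_model(X, y)
        A = np.column_stack([np.ones(15), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        est = [model.intercept, model.coefficients["mood_lag1"],
               model.coefficients["mood_lag2"]]
        assert np.allclose(est, beta, atol=1e-10)

    def test_history_model_recovers_ar1(self):
        coefs = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            y = np.zeros(43)
            for t in range(1, 43):
                y[t] = 0.8 * y[t - 1] + rng.normal(0, 0.3)
            X = pd.DataFrame({"mood_lag1": y[1:-1], "mood_lag2": y[:-2]})
            model = fit_history_model(X, y[2:])
            coefs.append(model.coefficients["mood_lag1"])
        assert abs(np.mean(coefs) - 0.8) < 0.2

    def test_history_needs_four_rows(self):
        X = pd.DataFrame({"mood_lag1": [1.0, 2.0], "mood_lag2": [0.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            fit_history_model(X, np.array([1.0, 2.0]))

    def test_target_independent_of_lags_gives_near_zero_coefficients(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            X = pd.DataFrame(
                {"mood_lag1": rng.normal(size=40), "mood_lag2": rng.normal(size=40)}
            )
            y = rng.normal(size=40)
            m = fit_history_model(X, y)
            ests.append([m.coefficients["mood_lag1"], m.coefficients["mood_lag2"]])
        assert np.abs(np.mean(ests, axis=0)).max() < 0.1


def test_gaussian_aic_monotone_in_sse():
    assert gaussian_aic(10.0, 20, 2) < gaussian_aic(20.0, 20, 2)
    assert gaussian_aic(10.0, 20, 2) < gaussian_aic(10.0, 20, 3)
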