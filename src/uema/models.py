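"""Personalized linear model families and PRESS-driven forward selection.

Four families are fit per participant and mood measure:

``mean``
    Intercept-only benchmark: predicts the training mean.
``history``
    OLS on the target's lag-1 and lag-2 values.
``stepAIC``
    Forward stepwise selection minimizing the Gaussian AIC.
``stepCV``
    Forward stepwise selection minimizing the leave-one-out cross-validated
    MSE, computed from a single fit per candidate via the PRESS statistic
    PRESS = sum_i (e_i / (1 - h_ii))^2, where e_i are in-sample residuals and
    h_ii the hat-matrix diagonal (leverages).  Selection adds, one at a time,
    the candidate that lowers the LOOCV MSE the most, and stops as soon as no
    candidate strictly improves it.

Both step families respect a complexity cap of floor(n_train / 5) predictors
(eight variables at 42 training days).  The selection loop maintains an
orthonormal basis of the current design, so evaluating every remaining
candidate at a step costs one matrix product rather than one regression each;
tests verify the shortcut against brute-force refits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVERAGE_TOL = 1e-8
TIE_TOL = 1e-12
COLLINEAR_TOL = 1e-10

FAMILIES = ("mean", "history", "stepAIC", "stepCV")


class DegenerateFitError(ValueError):
    """The requested least-squares fit is rank deficient."""


class DegenerateLeverageError(ValueError):
    """A leverage of (numerically) 1 makes the PRESS residual undefined."""


class InsufficientDataError(ValueError):
    """Too few rows to fit the requested family."""


@dataclass(frozen=True)
class SelectionStep:
    variable: str
    criterion: float


@dataclass
class SelectionTrace:
    """Ordered record of forward-selection steps.

    ``base_criterion`` is the intercept-only value; ``steps`` lists the
    variable added at each step together with the criterion value after the
    addition.  For ``cv_mse`` traces the criterion strictly decreases.
    """

    criterion: str  # "cv_mse" | "aic"
    base_criterion: float
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return [s.variable for s in self.steps]

    def values(self) -> list[float]:
        return [self.base_criterion] + [s.criterion for s in self.steps]


@dataclass
class LinearModel:
    """Fitted intercept + coefficients, with enough context to predict."""

    family: str
    intercept: float
    coefficients: dict[str, float]
    n_train: int
    trace: SelectionTrace | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        yhat = np.full(len(X), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            yhat += beta * X[name].to_numpy(dtype=float)
        return yhat

    def to_record(self) -> dict:
        rec = {
            "family": self.family,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "n_train": self.n_train,
        }
        if self.trace is not None:
            rec["trace"] = {
                "criterion": self.trace.criterion,
                "base": self.trace.base_criterion,
                "steps": [[s.variable, s.criterion] for s in self.trace.steps],
            }
        return rec


@dataclass
class OLSFit:
    """Least-squares fit of y on an intercept plus named columns."""

    names: list[str]
    intercept: float
    coef: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray
    sse: float
    n: int


def fit_ols(X: pd.DataFrame | np.ndarray, y: np.ndarray, names=None) -> OLSFit:
    """OLS with intercept; returns residuals and hat-matrix diagonal.

    Raises :class:`DegenerateFitError` naming the offending column when the
    design (including the intercept) is rank deficient, and requires strictly
    more rows than fitted parameters.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xmat = X.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        if Xmat.ndim == 1:
            Xmat = Xmat[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(Xmat.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xmat.shape
    if n <= p:
        raise InsufficientDataError(f"need more than {p} rows, got {n}")
    A = np.column_stack([np.ones(n), Xmat])
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(A, axis=0)
    small = diag < 1e-10 * np.maximum(scale, 1.0)
    if small.any():
        j = int(np.argmax(small))
        col = "intercept" if j == 0 else names[j - 1]
        raise DegenerateFitError(f"rank-deficient design: column {col!r}")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - A @ beta
    lev = np.einsum("ij,ij->i", Q, Q)
    return OLSFit(
        names=names,
        intercept=float(beta[0]),
        coef=beta[1:],
        residuals=resid,
        leverages=lev,
        sse=float(resid @ resid),
        n=n,
    )


def press_cv_mse(fit: OLSFit) -> float:
    """LOOCV mean squared error from one fit, via the PRESS statistic.

    cv_mse = (1/n) * sum_i (e_i / (1 - h_ii))^2.  Leverages numerically at 1
    (an observation that fully determines its own fitted value) make the
    left-out residual undefined and raise :class:`DegenerateLeverageError`.
    """
    if np.any(fit.leverages >= 1.0 - LEVERAGE_TOL):
        raise DegenerateLeverageError(
            "leverage numerically 1: left-out prediction undefined"
        )
    loo = fit.residuals / (1.0 - fit.leverages)
    return float(np.mean(loo**2))


def cap(n_train: int) -> int:
    """Maximum number of selected predictors: floor(n_train / 5).

    With fewer than 5 training rows the cap is 0 and the intercept-only model
    is forced.  42 training days allow at most 8 variables.
    """
    if n_train < 5:
        return 0
    return n_train // 5


def gaussian_aic(sse: float, n: int, k: int) -> float:
    """AIC of a Gaussian linear model with sigma^2 profiled out.

    ``n * ln(SSE/n) + 2 * (k + 2)``: k slope parameters plus intercept and
    variance.  Additive constants are irrelevant to selection and omitted.
    """
    return n * math.log(max(sse, 1e-300) / n) + 2.0 * (k + 2)


def _forward_select(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    max_vars: int,
    criterion: str,
) -> tuple[list[int], SelectionTrace]:
    """Greedy forward selection over the columns of X.

    Maintains an orthonormal basis Q of the current design; for a candidate
    column c, its orthogonal complement u = c - Q Q^T c updates residuals as
    e - u (u.y)/|u|^2 and leverages as h + u^2/|u|^2, so all candidates are
    scored with two matrix products per step.  Collinear candidates and
    candidates producing leverage 1 are skipped.  Ties within 1e-12 break by
    column order; selection stops when no candidate strictly improves the
    criterion or the cap is reached.
    """
    n, p = X.shape
    Q = np.full((n, 1), 1.0 / math.sqrt(n))
    e = y - y.mean()
    h = np.full(n, 1.0 / n)
    col_norm2 = np.einsum("ij,ij->j", X, X)

    if criterion == "cv_mse":
        if np.any(h >= 1.0 - LEVERAGE_TOL):
            raise DegenerateLeverageError("intercept-only fit has leverage 1")
        current = float(np.mean((e / (1.0 - h)) ** 2))
    elif criterion == "aic":
        current = gaussian_aic(float(e @ e), n, 0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    trace = SelectionTrace(criterion=criterion, base_criterion=current)

    selected: list[int] = []
    remaining = np.ones(p, dtype=bool)
    while len(selected) < max_vars and remaining.any():
        idx = np.flatnonzero(remaining)
        C = X[:, idx]
        U = C - Q @ (Q.T @ C)
        nu = np.einsum("ij,ij->j", U, U)
        ok = nu > COLLINEAR_TOL * np.maximum(col_norm2[idx], 1.0)
        nu_safe = np.where(ok, nu, 1.0)
        proj = (U.T @ y) / nu_safe
        E = e[:, None] - U * proj[None, :]
        H = h[:, None] + U**2 / nu_safe[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            if criterion == "cv_mse":
                denom = 1.0 - H
                valid = ok & (H.max(axis=0) < 1.0 - LEVERAGE_TOL)
                scores = np.mean((E / denom) ** 2, axis=0)
            else:
                valid = ok
                sse_new = np.einsum("ij,ij->j", E, E)
                k_new = len(selected) + 1
                scores = np.array(
                    [gaussian_aic(s, n, k_new) for s in sse_new], dtype=float
                )
        scores = np.where(valid, scores, np.inf)
        if not np.isfinite(scores).any():
            break
        best = float(np.min(scores))
        if not best < current:
            break
        j_local = int(np.flatnonzero(scores <= best + TIE_TOL)[0])
        j = int(idx[j_local])
        # accept
        q = U[:, j_local] / math.sqrt(nu[j_local])
        Q = np.column_stack([Q, q])
        e = E[:, j_local]
        h = H[:, j_local]
        current = best
        selected.append(j)
        remaining[j] = False
        trace.steps.append(SelectionStep(names[j], current))
    return selected, trace


def _refit(X: np.ndarray, y: np.ndarray, names: list[str], selected: list[int],
           family: str, trace: SelectionTrace) -> LinearModel:
    if not selected:
        return LinearModel(family, float(np.mean(y)), {}, len(y), trace)
    fit = fit_ols(X[:, selected], y, names=[names[j] for j in selected])
    return LinearModel(
        family,
        fit.intercept,
        {name: float(c) for name, c in zip(fit.names, fit.coef)},
        len(y),
        trace,
    )


def _as_matrix(X: pd.DataFrame | np.ndarray, names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, (list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])])


def forward_select_cv(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_vars: int | None = None,
    names=None,
) -> LinearModel:
    """Forward stepwise regression minimizing PRESS-based LOOCV MSE.

    Starts from the intercept-only model; at each step adds the candidate
    with the lowest resulting LOOCV MSE, provided it is strictly below the
    current value; stops otherwise or at the complexity cap
    (``floor(n/5)`` by default).
    """
    Xmat, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise InsufficientDataError(f"need >= 3 rows, got {len(y)}")
    if max_vars is None:
        max_vars = cap(len(y))
    max_vars = min(max_vars, max(0, len(y) - 2))
    selected, trace = _forward_select(Xmat, y, names, max_vars, "cv_mse")
    return _refit(Xmat, y, names, selected, "stepCV", trace)


def forward_select_aic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_vars: int | None = None,
    names=None,
) -> LinearModel:
    """Forward stepwise regression minimizing the Gaussian AIC."""
    Xmat, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise InsufficientDataError(f"need >= 3 rows, got {len(y)}")
    if max_vars is None:
        max_vars = cap(len(y))
    max_vars = min(max_vars, max(0, len(y) - 2))
    selected, trace = _forward_select(Xmat, y, names, max_vars, "aic")
    return _refit(Xmat, y, names, selected, "stepAIC", trace)


def fit_mean_model(y: np.ndarray) -> LinearModel:
    """Intercept-only benchmark: predicts the training mean."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise InsufficientDataError(f"mean model needs >= 2 rows, got {len(y)}")
    return LinearModel("mean", float(np.mean(y)), {}, len(y))


def fit_history_model(X: pd.DataFrame, y: np.ndarray) -> LinearModel:
    """Benchmark regression on the target's own lag-1 and lag-2 values.

    Collinear lags fall back to the minimum-norm least-squares solution.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise InsufficientDataError(f"history model needs >= 4 rows, got {len(y)}")
    lags = X[["mood_lag1", "mood_lag2"]].to_numpy(dtype=float)
    A = np.column_stack([np.ones(len(y)), lags])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(
        "history",
        float(beta[0]),
        {"mood_lag1": float(beta[1]), "mood_lag2": float(beta[2])},
        len(y),
    )


def fit_family(family: str, X: pd.DataFrame, y: np.ndarray) -> LinearModel:
    """Dispatch: fit one of the four model families on a training table."""
    if family == "mean":
        return fit_mean_model(y)
    if family == "history":
        return fit_history_model(X, y)
    if family == "stepCV":
        return forward_select_cv(X, y)
    if family == "stepAIC":
        return forward_select_aic(X, y)
    raise ValueError(f"unknown model family {family!r}")


def models_to_jsonl(records: list[dict], path) -> None:
    """Serialize fitted-model records (participant x measure x family) to JSON lines."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
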