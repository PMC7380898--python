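"""Propensity-score estimation: logistic regression by Newton-Raphson MLE.

The propensity score is the conditional probability of receiving the treatment
(the honorary title) given the five pre-treatment profile covariates, modeled
as logit p = b0 + sum_j b_j x_j. The fit is plain maximum likelihood - Newton
iterations with step-halving so the log-likelihood never decreases - with no
regularization; perfect separation is detected and reported rather than
silently penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_GRAD_TOL = 1e-8
_MAX_ITER = 100
# |linear predictor| beyond which fitted probabilities are numerically 0/1;
# reaching it without gradient convergence signals separation
_SEPARATION_ETA = 30.0


@dataclass
class PropensityModel:
    """A fitted logistic treatment-assignment model."""

    intercept: float
    coefficients: np.ndarray
    covariate_names: list[str]
    converged: bool
    n_iterations: int
    log_likelihood: float
    std_errors: np.ndarray | None = None
    separation_detected: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.covariate_names):
            raise ValueError("one coefficient required per covariate name")

    @property
    def params(self) -> np.ndarray:
        """Intercept followed by slopes."""
        return np.concatenate([[self.intercept], self.coefficients])

    def dump(self, path) -> None:
        """Key-value text dump (name: coefficient)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"intercept: {self.intercept!r}\n")
            for name, b in zip(self.covariate_names, self.coefficients):
                fh.write(f"{name}: {b!r}\n")
            fh.write(f"converged: {self.converged}\n")
            fh.write(f"log_likelihood: {self.log_likelihood!r}\n")


def _design(covariates: pd.DataFrame, names: list[str]) -> np.ndarray:
    X = covariates[names].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log(1+e^eta) computed stably on both tails
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_propensity(
    covariates: pd.DataFrame,
    treated: np.ndarray | pd.Series,
    log1p_counts: bool = False,
) -> PropensityModel:
    """Maximum-likelihood logistic fit of treatment on covariates.

    Parameters
    ----------
    covariates : DataFrame
        One row per physician, pre-treatment covariate columns (the month-0
        cumulative snapshot).
    treated : array of 0/1
        Treatment flags, one per physician.
    log1p_counts : bool
        If True, apply log1p to every covariate before fitting (an optional
        variance-stabilizing switch for the heavy-tailed counts; off by
        default).

    Raises
    ------
    ValueError
        If the treatment flag is degenerate (all 0 or all 1) or covariates
        contain missing values.
    """
    y = np.asarray(treated, dtype=float)
    if y.min() < 0 or y.max() > 1 or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("treated flags must be binary 0/1")
    if y.sum() == 0:
        raise ValueError("degenerate treatment flag: no treated physicians (all 0)")
    if y.sum() == len(y):
        raise ValueError("degenerate treatment flag: no control physicians (all 1)")

    names = list(covariates.columns)
    if covariates[names].isna().any().any():
        raise ValueError("missing covariate values are not allowed")
    work = covariates.copy()
    if log1p_counts:
        work = np.log1p(work)
    X = _design(work, names)
    n, p = X.shape

    beta = np.zeros(p)
    ll = _loglik(beta, X, y)
    converged = False
    separation = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(cand, X, y)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = _loglik(beta, X, y)
        # monotone-diverging linear predictor without a vanishing gradient
        # is the classic perfect-separation signature
        if np.max(np.abs(X @ beta)) > _SEPARATION_ETA:
            mu_b = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -700, 700)))
            if np.max(np.abs(X.T @ (y - mu_b))) >= _GRAD_TOL:
                separation = True
                break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = X.T @ (X * w[:, None])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    return PropensityModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        covariate_names=names,
        converged=converged and not separation,
        n_iterations=it,
        log_likelihood=_loglik(beta, X, y),
        std_errors=se,
        separation_detected=separation,
    )


def predict_ps(
    model: PropensityModel,
    covariates: pd.DataFrame,
    log1p_counts: bool = False,
) -> np.ndarray:
    """Predicted treatment probabilities, strictly inside (0, 1).

    Covariate columns must match the model's covariate names; a mismatch is
    reported with the missing and extra names.
    """
    have = set(covariates.columns)
    want = set(model.covariate_names)
    if have != want:
        raise ValueError(
            "covariate columns do not match the fitted model: "
            f"missing={sorted(want - have)}, extra={sorted(have - want)}"
        )
    work = covariates[model.covariate_names]
    if log1p_counts:
        work = np.log1p(work)
    eta = model.intercept + work.to_numpy(dtype=float) @ model.coefficients
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    eps = np.finfo(float).eps
    return np.clip(p, eps, 1.0 - eps)
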