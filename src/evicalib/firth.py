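"""Firth bias-reduced logistic regression of a binary outcome on one score.

Ordinary logistic maximum likelihood diverges under separation (a score
value that perfectly splits benign from pathogenic variants) and is badly
biased with sparse outcomes — both routine in per-gene variant sets.
Firth's correction maximizes the Jeffreys-penalized log-likelihood

    l*(b) = l(b) + 0.5 * ln det I(b),        I(b) = X' W X,

with W = diag(pi_i (1 - pi_i)), which always has a finite maximizer.  The
solver is a Newton iteration on the modified score

    U*_j = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ij,

where h_i is the i-th diagonal of the weighted hat matrix, with
step-halving to keep l* non-decreasing.

Only the single-covariate model (intercept + one score) is fit: the
calibration procedure models one predictor at a time.  Scores are
standardized internally and the coefficients back-transformed, which is
exact for this penalty (rescaling the design shifts ln det I by a constant
that does not depend on b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["FirthFit", "fit_firth_logistic", "fit_firth_intercept", "SingleClassError"]

# Solver defaults: coefficient-change and modified-score tolerances, Newton
# iteration cap, and step-halvings allowed per iteration.
DEFAULT_TOL_BETA = 1e-8
DEFAULT_TOL_SCORE = 1e-6
DEFAULT_MAX_ITER = 100
DEFAULT_MAX_HALVINGS = 20


class SingleClassError(ValueError):
    """Raised when the outcome vector contains only one class."""


@dataclass(frozen=True)
class FirthFit:
    """Result of a penalized logistic fit of class (pathogenic = 1) on a score.

    ``beta0``/``beta1`` are on the logit scale (per score unit); standard
    errors come from the inverse penalized Fisher information at the optimum
    and serve as diagnostics only.  ``loglik`` is the penalized
    log-likelihood l* at the optimum.
    """

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    loglik: float
    converged: bool
    n_iter: int
    n_cases: int
    n_controls: int

    def predict_proba(self, score: float | np.ndarray) -> float | np.ndarray:
        """Predicted probability of the pathogenic class at ``score``."""
        from scipy.special import expit

        return expit(self.beta0 + self.beta1 * np.asarray(score, dtype=float))


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log pi = -log(1 + e^-eta), log(1-pi) = -log(1 + e^eta)
    ll = -(np.logaddexp(0.0, -eta)[y == 1].sum() + np.logaddexp(0.0, eta)[y == 0].sum())
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = pi * (1.0 - pi)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    tol_beta: float = DEFAULT_TOL_BETA,
    tol_score: float = DEFAULT_TOL_SCORE,
    max_halvings: int = DEFAULT_MAX_HALVINGS,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Newton/step-halving maximizer of the Jeffreys-penalized likelihood.

    Returns (beta, covariance, penalized loglik, converged, iterations).
    """
    p = X.shape[1]
    beta = np.zeros(p)
    ll = _penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1.0 - pi)
        Xw = X * w[:, None]
        info = Xw.T @ X
        info_inv = np.linalg.inv(info)
        # h_i = w_i * x_i' I^{-1} x_i (diagonal of the weighted hat matrix)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        u_star = X.T @ (y - pi + h * (0.5 - pi))
        step = info_inv @ u_star
        # step-halve until l* does not decrease
        new_beta = beta + step
        new_ll = _penalized_loglik(X, y, new_beta)
        halvings = 0
        while new_ll < ll and halvings < max_halvings:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new_ll = _penalized_loglik(X, y, new_beta)
        delta = np.max(np.abs(new_beta - beta))
        beta, ll = new_beta, new_ll
        if delta < tol_beta or np.max(np.abs(u_star)) < tol_score:
            converged = True
            break
    # covariance at the optimum from the (unpenalized-form) Fisher information
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = pi * (1.0 - pi)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, cov, ll, converged, it


def _fit_arrays(
    x: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    tol_beta: float = DEFAULT_TOL_BETA,
    tol_score: float = DEFAULT_TOL_SCORE,
) -> tuple[float, float, bool]:
    """Lean fit path for resampling loops: returns (beta0, beta1, converged).

    Skips standard-error bookkeeping; assumes x, y are clean float arrays
    with both classes present.
    """
    m = x.mean()
    s = x.std()
    if s == 0.0:
        s = 1.0
    z = (x - m) / s
    X = np.column_stack((np.ones_like(z), z))
    beta, _, _, converged, _ = _firth_newton(
        X, y, max_iter=max_iter, tol_beta=tol_beta, tol_score=tol_score
    )
    b1 = beta[1] / s
    b0 = beta[0] - beta[1] * m / s
    return b0, b1, converged


def fit_firth_logistic(
    scores,
    labels,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    tol_beta: float = DEFAULT_TOL_BETA,
    tol_score: float = DEFAULT_TOL_SCORE,
    max_halvings: int = DEFAULT_MAX_HALVINGS,
) -> FirthFit:
    """Fit pathogenicity (label 1) on a single predictor score.

    Missing scores must be removed upstream; both classes must be present.
    Estimates are finite even under complete separation.

    Raises
    ------
    SingleClassError
        If all labels are identical.
    ValueError
        On length mismatch or non-finite scores.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite (remove missing values upstream)")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("labels must be 0 or 1")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise SingleClassError("single-class input: need at least one of each class")

    m = x.mean()
    s = x.std()
    if s == 0.0:
        s = 1.0
    z = (x - m) / s
    X = np.column_stack((np.ones_like(z), z))
    beta, cov, ll, converged, n_iter = _firth_newton(
        X,
        y,
        max_iter=max_iter,
        tol_beta=tol_beta,
        tol_score=tol_score,
        max_halvings=max_halvings,
    )
    # back-transform from standardized to raw score scale; the penalty
    # determinant picks up a factor s^2, so l*_raw = l*_std + ln s
    a0, a1 = beta
    b1 = a1 / s
    b0 = a0 - a1 * m / s
    ll = ll + math.log(s)
    r = m / s
    var_b0 = cov[0, 0] + r * r * cov[1, 1] - 2.0 * r * cov[0, 1]
    var_b1 = cov[1, 1] / (s * s)
    return FirthFit(
        beta0=float(b0),
        beta1=float(b1),
        se_beta0=float(math.sqrt(max(var_b0, 0.0))),
        se_beta1=float(math.sqrt(max(var_b1, 0.0))),
        loglik=float(ll),
        converged=bool(converged),
        n_iter=n_iter,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def fit_firth_intercept(labels) -> float:
    """Intercept-only Firth fit (slope fixed out); returns beta0.

    The penalized optimum has the closed form logit((s + 1/2) / (n + 1))
    with s successes out of n, hence is finite even when all labels agree;
    the solver iterates to it rather than shortcutting, so the closed form
    remains an independent check.
    """
    y = np.asarray(labels, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("labels must be a non-empty 1-D array")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("labels must be 0 or 1")
    X = np.ones((len(y), 1))
    beta, _, _, converged, _ = _firth_newton(X, y)
    if not converged:  # pragma: no cover - 1-D concave problem always converges
        raise RuntimeError("intercept-only Firth fit did not converge")
    return float(beta[0])
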