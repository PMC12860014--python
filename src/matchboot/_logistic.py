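"""Newton/IRLS logistic regression with an automatic ridge fallback.

Used both by propensity-score estimation and by the binary/categorical
conditional models inside chained-equation imputation.  The primary path is
plain maximum likelihood; separation or a singular information matrix
triggers a refit with a small L2 penalty (never silently — the result
records which path produced it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

_MAX_ABS_COEF = 30.0  # |beta| beyond this on any coordinate => treat as separation


@dataclass
class LogisticFit:
    coef: np.ndarray  # includes intercept as first element
    converged: bool
    used_ridge: bool
    n_iter: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coef)


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int, tol: float):
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    penalty = np.full(p, ridge)
    penalty[0] = 0.0  # never penalize the intercept
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - penalty * beta
        H = (X * w[:, None]).T @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False, it
        # damped Newton: halve until the step is finite and bounded
        scale = 1.0
        while scale > 1e-4 and not np.all(np.isfinite(beta + scale * step)):
            scale *= 0.5
        beta = beta + scale * step
        if not np.all(np.isfinite(beta)):
            return beta, False, it
        if np.max(np.abs(step)) < tol:
            return beta, True, it
    return beta, False, max_iter


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge_fallback: float = 1e-4,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit logit(P(y=1)) = X beta; X must already carry an intercept column.

    Falls back to ridge (lambda = ``ridge_fallback``) when the ML fit fails
    to converge, blows up (separation), or hits a singular Hessian.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta, converged, n_iter = _irls(X, y, ridge=0.0, max_iter=max_iter, tol=tol)
    max_slope = float(np.max(np.abs(beta[1:]))) if len(beta) > 1 else 0.0
    ok = converged and np.all(np.isfinite(beta)) and max_slope < _MAX_ABS_COEF
    if ok:
        return LogisticFit(coef=beta, converged=True, used_ridge=False, n_iter=n_iter)
    logger.debug("ML logistic fit unstable; refitting with ridge %g", ridge_fallback)
    beta, converged, n_iter = _irls(X, y, ridge=ridge_fallback, max_iter=2 * max_iter, tol=tol)
    if not np.all(np.isfinite(beta)):
        # last resort: heavier ridge; keeps bootstrap replicates from crashing
        beta, converged, n_iter = _irls(X, y, ridge=1.0, max_iter=2 * max_iter, tol=tol)
    return LogisticFit(coef=beta, converged=converged, used_ridge=True, n_iter=n_iter)


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(len(X)), X])
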