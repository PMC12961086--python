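"""Penalized IRLS core for binomial-logit fits.

All model fitting in the package goes through :func:`irls`.  The solver
maximizes the (optionally quadratically penalized) Bernoulli
log-likelihood with a logit link by iteratively reweighted least squares
with step-halving, so the objective is non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

# Linear predictors are clipped to keep expit away from exact 0/1.
_ETA_MAX = 30.0


@dataclass
class IRLSFit:
    coef: np.ndarray
    vcov: np.ndarray          # inverse of the (penalized) Fisher information
    llf: float                # unpenalized log-likelihood at the optimum
    penalized_llf: float
    fitted: np.ndarray        # per-row probabilities
    converged: bool
    n_iter: int
    edf: float                # trace of the hat matrix (= n params if unpenalized)
    separation: bool = False
    eta: np.ndarray = field(default=None, repr=False)


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Log-likelihood of binary y under logit(p) = eta, numerically stable."""
    # log L = sum y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def irls(
    X: np.ndarray,
    y: np.ndarray,
    penalty: np.ndarray | None = None,
    offset: np.ndarray | float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    separation_bound: float = 15.0,
) -> IRLSFit:
    """Fit a binomial-logit model, optionally with a quadratic penalty.

    Parameters
    ----------
    X : (n, p) model matrix.
    y : (n,) binary response.
    penalty : (p, p) positive semi-definite penalty matrix S; the objective
        is loglik(beta) - 0.5 * beta' S beta.  None means unpenalized ML.
    offset : fixed additive component of the linear predictor.
    separation_bound : if any coefficient exceeds this magnitude the fit is
        flagged as (quasi-)separated; meaningful on standardized covariates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("response must be binary 0/1")
    S = np.zeros((p, p)) if penalty is None else np.asarray(penalty, dtype=float)

    beta = np.zeros(p)
    eta = X @ beta + offset
    mu = expit(eta)
    obj = bernoulli_loglik(y, eta) - 0.5 * beta @ S @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        # working response for the penalized normal equations
        z = (eta - offset) + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + S
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        # step-halving: never decrease the penalized objective
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand + offset, -_ETA_MAX, _ETA_MAX)
            obj_c = bernoulli_loglik(y, eta_c) - 0.5 * cand @ S @ cand
            if obj_c >= obj - 1e-12:
                break
            step *= 0.5
        beta = beta + step * (beta_new - beta)
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = expit(eta)
        obj_new = bernoulli_loglik(y, eta) - 0.5 * beta @ S @ beta
        if abs(obj_new - obj) <= tol * (abs(obj) + 1.0):
            obj = obj_new
            converged = True
            break
        obj = obj_new

    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    XtW = X.T * w
    A = XtW @ X + S
    try:
        vcov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(A)
    # edf = tr[(X'WX + S)^{-1} X'WX]; equals p when S = 0
    edf = float(np.trace(vcov @ (XtW @ X)))
    llf = bernoulli_loglik(y, eta)
    return IRLSFit(
        coef=beta,
        vcov=vcov,
        llf=llf,
        penalized_llf=obj,
        fitted=mu,
        converged=converged,
        n_iter=it,
        edf=edf,
        separation=bool(np.max(np.abs(beta)) > separation_bound),
        eta=eta,
    )
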