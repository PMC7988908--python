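"""Firth bias-reduced logistic regression.

Ordinary logistic regression breaks down exactly where gene-burden tests
live: sparse 2x2-ish designs where all carriers can be cases (complete
separation), sending the MLE to infinity.  Firth's correction maximizes the
Jeffreys-prior-penalized log-likelihood

    l*(beta) = l(beta) + 0.5 * log det I(beta),    I = X' W X,  W = diag(p(1-p))

whose maximizer is always finite.  The p-value reported for the coefficient
of interest comes from the penalized likelihood-ratio test (chi-square, 1
df), which behaves better than Wald in sparse tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .errors import ConvergenceError, ValidationError


@dataclass
class FirthResult:
    beta: float  # coefficient of the column of interest
    se: float
    p: Optional[float]
    loglik: float  # penalized log-likelihood at the optimum
    coefficients: np.ndarray  # full vector incl. intercept
    converged: bool
    n_iter: int
    flagged: Optional[str] = None  # e.g. degenerate carrier column


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood via logaddexp for numerical safety
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    W = p * (1.0 - p)
    sign, logdet = np.linalg.slogdet((X * W[:, None]).T @ X)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_fit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
):
    """Newton iteration on the Firth-modified score; returns (beta, vcov, ll, it)."""
    n, k = X.shape
    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, beta)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        W = p * (1.0 - p)
        XW = X * W[:, None]
        info = XW.T @ X
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(U)) < tol and it > 1:
            return beta, info_inv, ll, it
        step = info_inv @ U
        # step-halving keeps the penalized likelihood non-decreasing
        new_ll = -np.inf
        for _ in range(25):
            cand = beta + step
            new_ll = _penalized_loglik(X, y, cand)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll = new_ll
    eta = X @ beta
    p = expit(eta)
    U = X.T @ (y - p)
    raise ConvergenceError(
        f"Firth fit did not converge in {max_iter} iterations",
        beta=beta,
        grad_norm=float(np.max(np.abs(U))),
        n_iter=max_iter,
    )


def firth_logistic(
    x: Sequence[int],
    y: Sequence[int],
    covariates: Optional[np.ndarray] = None,
    max_iter: int = 100,
) -> FirthResult:
    """Fit case/control status on a carrier indicator (plus covariates).

    ``x`` is the column of interest (gene carrier status), ``y`` the binary
    phenotype.  An intercept is always added.  A constant ``x`` cannot be
    estimated and is returned flagged instead of fitted.  The p-value is a
    penalized LRT: twice the gap between the full and the x-dropped
    penalized log-likelihoods against chi-square(1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equally long")
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValidationError("y must be binary 0/1")
    n = len(y)
    cols = [np.ones(n), x]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        cols.extend(covariates.T)
    X = np.column_stack(cols)
    if np.ptp(x) == 0:
        return FirthResult(
            beta=float("nan"), se=float("nan"), p=None, loglik=float("nan"),
            coefficients=np.full(X.shape[1], np.nan), converged=False, n_iter=0,
            flagged="carrier status is constant across samples",
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")

    beta, vcov, ll_full, n_iter = _firth_fit(X, y, max_iter=max_iter)
    X0 = np.delete(X, 1, axis=1)  # drop the carrier column
    _, _, ll_null, _ = _firth_fit(X0, y, max_iter=max_iter)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    return FirthResult(
        beta=float(beta[1]),
        se=float(np.sqrt(vcov[1, 1])),
        p=float(chi2.sf(lrt, df=1)),
        loglik=ll_full,
        coefficients=beta,
        converged=True,
        n_iter=n_iter,
    )
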