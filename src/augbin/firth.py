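"""Logistic regression by ML and by Firth's penalized ML, with separation
diagnostics.

Firth's estimator maximizes the Jeffreys-penalized log-likelihood
``l(beta) + 0.5 * log|I(beta)|``.  It is computed by iteratively reweighted
least squares on the modified score

    U*(beta) = X' (y - pi + h * (1/2 - pi)),

where ``h`` are the leverages of the weighted hat matrix.  Firth estimates
are finite even under perfect separation; plain ML estimates are not, and
such fits are returned with ``converged=False`` and
``separation_detected=True`` rather than as silent garbage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.special import expit

__all__ = ["FirthFit", "fit_logistic", "detect_separation", "DesignError"]

#: coefficient-norm surrogate for a divergent ML iterate
_DIVERGENCE_NORM = 1e3
_LOGLIK_STALL = 1e-10


class DesignError(ValueError):
    """Raised for unusable design matrices (e.g. rank deficiency)."""


@dataclass
class FirthFit:
    """A (penalized) logistic regression fit.

    ``cov`` is the inverse Fisher information at the optimum; for penalized
    fits this is the conventional Firth covariance.  ``penalized_loglik``
    is the plain log-likelihood when ``penalty='none'``.
    """

    beta: np.ndarray
    cov: np.ndarray
    penalized_loglik: float
    converged: bool
    n_iter: int
    separation_detected: bool
    penalty: str = "firth"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray, penalized: bool) -> float:
    eta = X @ beta
    # numerically stable log-likelihood: sum y*eta - log(1 + exp(eta))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if penalized:
        pi = expit(eta)
        w = np.clip(pi * (1.0 - pi), 1e-300, None)
        info = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        ll += 0.5 * logdet
    return ll


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty: str = "firth",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FirthFit:
    """Fit a logistic regression by ML or Firth PML.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Full-column-rank design matrix (include the intercept explicitly).
    y : ndarray of 0/1, shape (n,)
    penalty : {'none', 'firth'}
    max_iter, tol
        IRLS is stopped when the max absolute (modified) score component
        drops below ``tol``.

    Returns
    -------
    FirthFit
        Under ``penalty='none'`` with separated data the fit carries the
        last finite iterate with ``converged=False`` and
        ``separation_detected=True``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if penalty not in ("none", "firth"):
        raise ValueError(f"penalty must be 'none' or 'firth', got {penalty!r}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if n < p:
        raise DesignError(f"n={n} rows < p={p} columns")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")

    firth = penalty == "firth"
    beta = np.zeros(p)
    ll = _loglik(X, y, beta, firth)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        w = np.clip(pi * (1.0 - pi), 1e-12, None)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        if firth:
            h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
            score = X.T @ (y - pi + h * (0.5 - pi))
        else:
            score = X.T @ (y - pi)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        # damped step: halve until the objective does not decrease
        new_beta = beta + step
        new_ll = _loglik(X, y, new_beta, firth)
        n_halve = 0
        while new_ll < ll - 1e-12 and n_halve < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X, y, new_beta, firth)
            n_halve += 1
        improvement = new_ll - ll
        beta, ll = new_beta, new_ll
        if not firth and np.linalg.norm(beta) > _DIVERGENCE_NORM and improvement < _LOGLIK_STALL:
            separated = True
            break
    if firth and not converged:
        # IRLS can stall on extreme geometries; the modified score is the
        # exact gradient of the penalized objective, so polish with BFGS.
        from scipy.optimize import minimize

        def neg_obj(b):
            return -_loglik(X, y, b, True)

        def neg_grad(b):
            pi_ = expit(X @ b)
            w_ = np.clip(pi_ * (1.0 - pi_), 1e-12, None)
            inv_ = np.linalg.pinv(X.T @ (X * w_[:, None]))
            h_ = w_ * np.einsum("ij,jk,ik->i", X, inv_, X)
            return -(X.T @ (y - pi_ + h_ * (0.5 - pi_)))

        res = minimize(neg_obj, beta, jac=neg_grad, method="BFGS",
                       options={"gtol": tol / 10, "maxiter": 500})
        if -res.fun >= ll:
            beta, ll = res.x, -res.fun
        pi = expit(X @ beta)
        w = np.clip(pi * (1.0 - pi), 1e-12, None)
        info_inv = np.linalg.pinv(X.T @ (X * w[:, None]))
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - pi + h * (0.5 - pi))
        converged = bool(np.max(np.abs(score)) < 10 * tol)
    if not firth:
        if not converged:
            separated = separated or detect_separation(X, y)
        else:
            # ML can "converge" at a finite iterate under quasi-complete
            # separation because saturated probabilities kill the score
            pi = expit(X @ beta)
            if np.min(pi * (1.0 - pi)) < 1e-8:
                separated = detect_separation(X, y)
                if separated:
                    converged = False

    pi = expit(X @ beta)
    w = np.clip(pi * (1.0 - pi), 1e-12, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = 0.5 * (cov + cov.T)
    return FirthFit(
        beta=beta,
        cov=cov,
        penalized_loglik=ll,
        converged=converged,
        n_iter=it,
        separation_detected=separated,
        penalty=penalty,
    )


def detect_separation(X: np.ndarray, y: np.ndarray) -> bool:
    """Linear-program check for (quasi-)complete separation.

    Separation holds iff some direction ``b`` satisfies
    ``(2 y_i - 1) x_i' b >= 0`` for all rows with strict inequality
    somewhere; then the ML estimate is unbounded.  Solved as: maximize
    ``sum(s)`` over ``b`` free, ``0 <= s <= 1`` subject to
    ``(2y-1) X b >= s``; separation iff the optimum is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    signed = (2.0 * y - 1.0)[:, None] * X
    # variables: [b (p, free), s (n, in [0,1])]; constraint s - signed@b <= 0
    A_ub = np.hstack([-signed, np.eye(n)])
    b_ub = np.zeros(n)
    c = np.concatenate([np.zeros(p), -np.ones(n)])
    bounds = [(None, None)] * p + [(0.0, 1.0)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - highs is reliable on these LPs
        raise RuntimeError(f"separation LP failed: {res.message}")
    return bool(-res.fun > 1e-7)
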