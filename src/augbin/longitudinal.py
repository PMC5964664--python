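"""Repeated-measures fits of the continuous component: GLS (multivariate
normal likelihood, unstructured covariance) and GEE (identity link), plus
the small-sample sandwich-variance inflation of Morel, Bokossa & Neerchal
(MBN).

The mean model is saturated in time and treatment: one intercept and one
arm effect per visit, optionally a shared baseline slope.  This is the
minimal model that supports per-arm final-visit predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize

import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence, Unstructured

from .datasets import TrialDataset

__all__ = ["LongitudinalFit", "FitError", "fit_gls", "fit_gee", "mbn_correct"]


class FitError(RuntimeError):
    """Raised when a longitudinal fit cannot be computed."""


@dataclass
class LongitudinalFit:
    """Fitted repeated-measures model for the continuous outcomes.

    ``beta`` is laid out as ``[intercept_1..intercept_T, arm_1..arm_T,
    (baseline)]``.  ``Sigma`` is the T x T within-patient covariance (ML
    estimate for GLS, residual moment estimate for GEE).  ``cov_robust``
    and ``cov_mbn`` are only populated for GEE fits.
    """

    beta: np.ndarray
    Sigma: np.ndarray
    cov_model: np.ndarray
    fitter: str
    n_clusters: int
    p: int
    n_obs_total: int
    n_visits: int
    baseline_adjust: bool
    loglik: Optional[float] = None
    cov_robust: Optional[np.ndarray] = None
    cov_mbn: Optional[np.ndarray] = None

    def mean_at(self, arm: int, baseline: float = 0.0) -> np.ndarray:
        """Per-visit mean vector for the given arm (and baseline, if used)."""
        T = self.n_visits
        mu = self.beta[:T] + self.beta[T : 2 * T] * arm
        if self.baseline_adjust:
            mu = mu + self.beta[2 * T] * baseline
        return mu


def _design_rows(data: TrialDataset, baseline_adjust: bool) -> np.ndarray:
    """Per-patient full design, shape (n, T, p)."""
    n, T = data.y.shape
    p = 2 * T + (1 if baseline_adjust else 0)
    X = np.zeros((n, T, p))
    for t in range(T):
        X[:, t, t] = 1.0
        X[:, t, T + t] = data.arm
    if baseline_adjust:
        X[:, :, 2 * T] = data.baseline[:, None]
    return X


def _check_pd(Sigma: np.ndarray) -> None:
    if not np.all(np.linalg.eigvalsh(Sigma) > 0):
        raise FitError("estimated within-patient covariance is not positive definite")


def _pattern_groups(mask: np.ndarray):
    """Group patient indices by their visit-observation pattern."""
    keys = [tuple(row) for row in mask]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        if any(k):
            groups.setdefault(k, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def _gls_profile(theta: np.ndarray, X, y, groups, T, p, want_fit=False):
    """Profile negative log-likelihood over the Cholesky parameters of Sigma.

    Given Sigma, the mean coefficients solve the GLS normal equations; the
    returned value is -2 * the profiled Gaussian log-likelihood (without
    the 2*pi constant when only used for optimization).
    """
    L = np.zeros((T, T))
    il = np.tril_indices(T)
    L[il] = theta
    L[np.diag_indices(T)] = np.exp(np.diag(L))
    Sigma = L @ L.T

    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    pieces = []
    for key, idx in groups.items():
        obs = np.flatnonzero(key)
        sub = Sigma[np.ix_(obs, obs)]
        try:
            sub_inv = np.linalg.inv(sub)
            sign, logdet = np.linalg.slogdet(sub)
        except np.linalg.LinAlgError:
            return np.inf if not want_fit else (None, None, np.inf)
        if sign <= 0:
            return np.inf if not want_fit else (None, None, np.inf)
        Xo = X[idx][:, obs, :]  # (m, k, p)
        yo = y[idx][:, obs]  # (m, k)
        XtWX += np.einsum("mkp,kl,mlq->pq", Xo, sub_inv, Xo)
        XtWy += np.einsum("mkp,kl,ml->p", Xo, sub_inv, yo)
        pieces.append((idx, obs, sub_inv, logdet, Xo, yo))
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        raise FitError("fewer observations than mean parameters (singular GLS system)")
    nll = 0.0
    n_obs = 0
    for idx, obs, sub_inv, logdet, Xo, yo in pieces:
        r = yo - Xo @ beta
        quad = np.einsum("mk,kl,ml->m", r, sub_inv, r)
        m = len(idx)
        nll += 0.5 * (m * logdet + quad.sum() + m * len(obs) * np.log(2 * np.pi))
        n_obs += m * len(obs)
    if want_fit:
        return beta, Sigma, nll
    return nll


def fit_gls(data: TrialDataset, baseline_adjust: bool = False) -> LongitudinalFit:
    """Maximum-likelihood GLS fit with unstructured within-patient covariance.

    Uses every observed (possibly incomplete) visit vector.  For complete
    data under the saturated mean model the ML solution is closed form
    (visit-wise arm means, pooled residual covariance); otherwise the
    covariance Cholesky is profiled out numerically.
    """
    data.require_both_arms(min_per_arm=2)
    n, T = data.y.shape
    X = _design_rows(data, baseline_adjust)
    p = X.shape[2]
    mask = np.isfinite(data.y)
    if not mask.any(axis=1).all():
        keep = mask.any(axis=1)
        data_used = data.subset(np.flatnonzero(keep))
        return fit_gls(data_used, baseline_adjust)
    n_obs = int(mask.sum())
    if n_obs < p + T:
        raise FitError("too few observations for the requested mean model")

    if mask.all() and not baseline_adjust:
        # closed-form ML: saturated means + pooled residual covariance
        beta = np.zeros(p)
        resid = np.empty_like(data.y)
        for z in (0, 1):
            sel = data.arm == z
            means = data.y[sel].mean(axis=0)
            resid[sel] = data.y[sel] - means
            if z == 0:
                beta[:T] = means
            else:
                beta[T : 2 * T] = means - beta[:T]
        Sigma = resid.T @ resid / n
        _check_pd(Sigma)
        Sigma_inv = np.linalg.inv(Sigma)
        XtWX = np.einsum("mkp,kl,mlq->pq", X, Sigma_inv, X)
        cov_model = np.linalg.inv(XtWX)
        sign, logdet = np.linalg.slogdet(Sigma)
        quad = np.einsum("mk,kl,ml->m", resid, Sigma_inv, resid).sum()
        ll = -0.5 * (n * logdet + quad + n * T * np.log(2 * np.pi))
        return LongitudinalFit(
            beta=beta, Sigma=Sigma, cov_model=cov_model, fitter="GLS",
            n_clusters=n, p=p, n_obs_total=n_obs, n_visits=T,
            baseline_adjust=baseline_adjust, loglik=ll,
        )

    groups = _pattern_groups(mask)
    # start from pairwise-complete covariance (diagonal fallback)
    start = np.zeros((T, T))
    for s in range(T):
        for t in range(s, T):
            both = mask[:, s] & mask[:, t]
            if both.sum() > 2:
                ys = data.y[both, s] - data.y[both, s].mean()
                yt = data.y[both, t] - data.y[both, t].mean()
                start[s, t] = start[t, s] = float(np.mean(ys * yt))
    diag = np.diag(start).copy()
    diag[diag <= 0] = np.nanvar(data.y)
    start[np.diag_indices(T)] = diag
    if np.any(np.linalg.eigvalsh(start) <= 0):
        start = np.diag(diag)
    L0 = np.linalg.cholesky(start)
    L0[np.diag_indices(T)] = np.log(np.diag(L0))
    theta0 = L0[np.tril_indices(T)]

    args = (X, data.y, groups, T, p)
    res = minimize(_gls_profile, theta0, args=args, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    if not res.success:
        res2 = minimize(_gls_profile, res.x, args=args, method="BFGS")
        if res2.fun < res.fun:
            res = res2
    beta, Sigma, nll = _gls_profile(res.x, *args, want_fit=True)
    if beta is None:
        raise FitError("GLS covariance iterate not positive definite")
    _check_pd(Sigma)
    XtWX = np.zeros((p, p))
    for key, idx in groups.items():
        obs = np.flatnonzero(key)
        sub_inv = np.linalg.inv(Sigma[np.ix_(obs, obs)])
        Xo = X[idx][:, obs, :]
        XtWX += np.einsum("mkp,kl,mlq->pq", Xo, sub_inv, Xo)
    cov_model = np.linalg.inv(XtWX)
    return LongitudinalFit(
        beta=beta, Sigma=Sigma, cov_model=cov_model, fitter="GLS",
        n_clusters=n, p=p, n_obs_total=n_obs, n_visits=T,
        baseline_adjust=baseline_adjust, loglik=-nll,
    )


_COV_STRUCTS = {
    "independence": Independence,
    "exchangeable": Exchangeable,
    "unstructured": Unstructured,
}


def fit_gee(
    data: TrialDataset,
    baseline_adjust: bool = False,
    working_corr: str = "exchangeable",
) -> LongitudinalFit:
    """GEE fit (identity link) with cluster-robust sandwich covariance.

    Missing visits are dropped observation-wise.  ``cov_model`` holds the
    naive (model-based) covariance, ``cov_robust`` the sandwich.
    """
    if working_corr not in _COV_STRUCTS:
        raise ValueError(f"working_corr must be one of {sorted(_COV_STRUCTS)}")
    data.require_both_arms(min_per_arm=2)
    n, T = data.y.shape
    X_full = _design_rows(data, baseline_adjust)
    p = X_full.shape[2]
    mask = np.isfinite(data.y)
    if int(mask.sum()) < p + 1:
        raise FitError("too few observations for the requested mean model")

    rows = mask.ravel()
    Xl = X_full.reshape(n * T, p)[rows]
    yl = data.y.ravel()[rows]
    gl = np.repeat(np.arange(n), T)[rows]
    tl = np.tile(np.arange(T), n)[rows]

    model = sm.GEE(
        yl, Xl, groups=gl, time=tl,
        family=sm.families.Gaussian(),
        cov_struct=_COV_STRUCTS[working_corr](),
    )
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:  # statsmodels raises assorted numerical errors
        raise FitError(f"GEE fit failed: {exc}") from exc
    if not getattr(res, "converged", True):
        raise FitError("GEE did not converge")

    beta = np.asarray(res.params)
    cov_robust = np.asarray(res.cov_robust)
    cov_model = np.asarray(res.cov_naive)
    if not np.isfinite(cov_robust).all():
        raise FitError("GEE sandwich covariance undefined (degenerate clusters)")

    # residual moment estimate of the within-patient covariance
    fitted = np.einsum("ntp,p->nt", X_full, beta)
    resid = np.where(mask, data.y - fitted, np.nan)
    Sigma = np.empty((T, T))
    for s in range(T):
        for t in range(T):
            both = mask[:, s] & mask[:, t]
            if both.sum() < 2:
                raise FitError(f"too few complete pairs for visits ({s}, {t})")
            Sigma[s, t] = np.mean(resid[both, s] * resid[both, t])
    Sigma = 0.5 * (Sigma + Sigma.T)
    _check_pd(Sigma)

    return LongitudinalFit(
        beta=beta, Sigma=Sigma, cov_model=cov_model, fitter="GEE",
        n_clusters=n, p=p, n_obs_total=int(mask.sum()), n_visits=T,
        baseline_adjust=baseline_adjust,
        cov_robust=cov_robust,
    )


def mbn_correct(fit: LongitudinalFit) -> LongitudinalFit:
    """Small-sample inflation of the GEE sandwich covariance.

    With sandwich ``A``, model-based covariance ``B``, ``K`` clusters,
    ``N`` total observations and ``p`` mean parameters:

        cov_mbn = f * A + delta * xi * B
        f     = ((N - 1) / (N - p)) * (K / (K - 1))
        delta = min(0.5, p / (K - p))
        xi    = max(1, trace(B^-1 A) / p)

    The diagonal of ``cov_mbn`` dominates that of ``A`` elementwise.
    """
    if fit.fitter != "GEE" or fit.cov_robust is None:
        raise FitError("MBN correction requires a GEE fit with a sandwich covariance")
    K, p, N = fit.n_clusters, fit.p, fit.n_obs_total
    if K <= p:
        raise FitError(f"MBN correction undefined: K={K} clusters <= p={p} parameters")
    A = fit.cov_robust
    B = fit.cov_model
    f = ((N - 1) / (N - p)) * (K / (K - 1))
    delta = min(0.5, p / (K - p))
    xi = max(1.0, float(np.trace(np.linalg.solve(B, A))) / p)
    cov_mbn = f * A + delta * xi * B
    cov_mbn = 0.5 * (cov_mbn + cov_mbn.T)
    return replace(fit, cov_mbn=cov_mbn)
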