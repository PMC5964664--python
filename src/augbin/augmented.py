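"""The augmented binary estimator.

Instead of a logistic regression on the dichotomized responder flag, the
composite endpoint is modelled through its components: a multivariate
normal model for the continuous outcomes at the scheduled visits and a
logistic model per failure interval (the first interval depends on arm
only; later intervals additionally condition on the preceding continuous
outcome).  The joint factorization yields, for each patient standardized
to arm ``z``,

    p_i(z) = Pr(no failure in interval 1 | z)
             * E[ prod_t Pr(no failure in t | z, y_{t-1})
                  * 1{y_T >= c} | z ],

evaluated by Gauss-Hermite quadrature over the non-final visits with the
final-visit orthant in closed form (normal conditional CDF).  Treatment
effects on the arm-averaged probabilities carry delta-method CIs through
the block-diagonal covariance of the component fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional

import numpy as np
from scipy.special import expit, ndtr

from .datasets import AnalysisConfig, TrialDataset
from .effects import PROB_CLIP, EffectEstimate, delta_method_effects
from .firth import FirthFit, fit_logistic
from .longitudinal import FitError, LongitudinalFit, fit_gee, fit_gls, mbn_correct

__all__ = ["AugbinFit", "ResponseIntegrator", "fit_augmented_binary",
           "predict_response_probability", "joint_response_probability",
           "estimate_effect", "estimate_effects", "ComponentFitError"]


class ComponentFitError(FitError):
    """A component model failed; carries the component identity."""

    def __init__(self, component: str, cause: Exception):
        super().__init__(f"component {component!r} failed: {cause}")
        self.component = component
        self.cause = cause


@lru_cache(maxsize=16)
def _gh_grid(ndim: int, nodes: int):
    """Tensor Gauss-Hermite grid for an ndim standard-normal expectation."""
    x, w = np.polynomial.hermite.hermgauss(nodes)
    if ndim == 0:
        return np.zeros((1, 0)), np.ones(1)
    grids = np.meshgrid(*([x] * ndim), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    wts = np.ones(pts.shape[0])
    for k in range(ndim):
        wts *= np.meshgrid(*([w] * ndim), indexing="ij")[k].ravel()
    wts /= np.pi ** (ndim / 2)
    return pts, wts


class ResponseIntegrator:
    """Quadrature evaluator of the marginal responder probability.

    Precomputes everything that depends only on the within-patient
    covariance, the threshold and the node count, so repeated calls with
    perturbed mean / failure coefficients (delta-method gradients) stay
    cheap.  Non-final visits are integrated on a tensor Gauss-Hermite
    grid; the final-visit exceedance is the closed-form conditional-normal
    CDF.
    """

    def __init__(self, Sigma: np.ndarray, c: float, nodes: int = 40):
        Sigma = np.asarray(Sigma, dtype=float)
        T = Sigma.shape[0]
        self.T = T
        self.c = float(c)
        self.nodes = int(nodes)
        if T == 1:
            self.sd = float(np.sqrt(Sigma[0, 0]))
            return
        rest = slice(0, T - 1)
        Sig_rr = Sigma[rest, rest]
        Sig_Tr = Sigma[T - 1, rest]
        self.sol = np.linalg.solve(Sig_rr, Sig_Tr)
        cond_var = float(Sigma[T - 1, T - 1] - Sig_Tr @ self.sol)
        if cond_var <= 0:
            raise FitError("conditional variance of the final visit is not positive")
        self.cond_sd = np.sqrt(cond_var)
        L = np.linalg.cholesky(Sig_rr)
        pts, self.wts = _gh_grid(T - 1, nodes)
        self.z_rest = np.sqrt(2.0) * pts @ L.T  # (m, T-1), zero-mean draws

    def prob(self, mu: np.ndarray, eta_fail1: float,
             fail_coefs: List[np.ndarray], arm: int) -> float:
        mu = np.asarray(mu, dtype=float)
        if self.T == 1:
            p = (1.0 - expit(eta_fail1)) * ndtr((mu[0] - self.c) / self.sd)
            return float(np.clip(p, PROB_CLIP, 1 - PROB_CLIP))
        y_rest = mu[: self.T - 1] + self.z_rest
        cond_mean = mu[self.T - 1] + self.z_rest @ self.sol
        integrand = ndtr((cond_mean - self.c) / self.cond_sd)
        for t in range(1, self.T):
            g = np.asarray(fail_coefs[t - 1], dtype=float)
            eta = g[0] + g[1] * arm + g[2] * y_rest[:, t - 1]
            integrand = integrand * (1.0 - expit(eta))
        p = (1.0 - expit(eta_fail1)) * float(self.wts @ integrand)
        return float(np.clip(p, PROB_CLIP, 1 - PROB_CLIP))


def joint_response_probability(
    mu: np.ndarray,
    Sigma: np.ndarray,
    eta_fail1: float,
    fail_coefs: List[np.ndarray],
    arm: int,
    c: float,
    nodes: int = 40,
) -> float:
    """Marginal responder probability under the factorized joint model.

    ``fail_coefs[t]`` for t >= 1 holds ``(intercept, arm, prev-outcome)``
    coefficients of the interval-(t+1) failure model; ``eta_fail1`` is the
    interval-1 linear predictor already evaluated at ``arm``.
    """
    return ResponseIntegrator(Sigma, c, nodes).prob(mu, eta_fail1, fail_coefs, arm)


@dataclass
class AugbinFit:
    """Assembled joint model: continuous fit + per-interval failure fits.

    ``theta`` concatenates the continuous mean coefficients and the failure
    coefficients; ``cov_theta`` is block-diagonal over the component fits
    (MBN-corrected block for GEE when requested, model-based for GLS).
    ``Sigma`` is carried as a plug-in and is not part of ``theta``.
    """

    cont: LongitudinalFit
    fail_models: List[FirthFit]
    theta: np.ndarray
    cov_theta: np.ndarray
    threshold: float
    quadrature_nodes: int
    config: AnalysisConfig

    @property
    def separation_detected(self) -> bool:
        return any(f.separation_detected for f in self.fail_models)

    @property
    def integrator(self) -> ResponseIntegrator:
        if getattr(self, "_integrator", None) is None:
            self._integrator = ResponseIntegrator(
                self.cont.Sigma, self.threshold, self.quadrature_nodes
            )
        return self._integrator

    def _split_theta(self, theta: np.ndarray):
        p_cont = self.cont.beta.size
        parts = [theta[:p_cont]]
        off = p_cont
        for f in self.fail_models:
            k = f.beta.size
            parts.append(theta[off : off + k])
            off += k
        return parts

    def predict(self, arm: int, baseline: float = 0.0,
                theta: Optional[np.ndarray] = None) -> float:
        """Per-patient responder probability standardized to arm ``arm``."""
        if theta is None:
            theta = self.theta
        parts = self._split_theta(np.asarray(theta, dtype=float))
        beta_cont = parts[0]
        T = self.cont.n_visits
        mu = beta_cont[:T] + beta_cont[T : 2 * T] * arm
        if self.cont.baseline_adjust:
            mu = mu + beta_cont[2 * T] * baseline
        g1 = parts[1]
        eta1 = g1[0] + g1[1] * arm
        return self.integrator.prob(mu, eta1, parts[2:], arm)

    def pbar_fn(self, data: TrialDataset):
        """Closure mapping theta -> (pbar_1, pbar_0), standardized over all patients."""
        if self.cont.baseline_adjust:
            baselines = np.asarray(data.baseline, dtype=float)

            def fn(theta):
                p1 = float(np.mean([self.predict(1, b, theta) for b in baselines]))
                p0 = float(np.mean([self.predict(0, b, theta) for b in baselines]))
                return p1, p0

        else:

            def fn(theta):
                return self.predict(1, 0.0, theta), self.predict(0, 0.0, theta)

        return fn


def fit_augmented_binary(data: TrialDataset, config: AnalysisConfig) -> AugbinFit:
    """Fit all component models and assemble the joint parameter vector."""
    data.require_both_arms(min_per_arm=2)
    T = data.n_visits
    penalty = "firth" if config.firth else "none"

    try:
        if config.continuous_fitter == "GLS":
            cont = fit_gls(data, baseline_adjust=config.baseline_adjust)
            cont_cov = cont.cov_model
        else:
            cont = fit_gee(data, baseline_adjust=config.baseline_adjust)
            if config.mbn:
                cont = mbn_correct(cont)
                cont_cov = cont.cov_mbn
            else:
                cont_cov = cont.cov_robust
    except Exception as exc:
        raise ComponentFitError("continuous", exc) from exc

    fail_models: List[FirthFit] = []
    covs = [cont_cov]
    X1 = np.column_stack([np.ones(data.n_patients), data.arm])
    try:
        fail_models.append(fit_logistic(X1, data.d[:, 0], penalty=penalty))
    except Exception as exc:
        raise ComponentFitError("failure_interval_1", exc) from exc
    covs.append(fail_models[0].cov)
    for t in range(1, T):
        at_risk = (data.d[:, t - 1] == 0) & np.isfinite(data.y[:, t - 1])
        if at_risk.sum() < 4:
            raise ComponentFitError(
                f"failure_interval_{t + 1}",
                FitError(f"only {int(at_risk.sum())} patients at risk"),
            )
        Xt = np.column_stack(
            [np.ones(int(at_risk.sum())), data.arm[at_risk], data.y[at_risk, t - 1]]
        )
        try:
            fail_models.append(fit_logistic(Xt, data.d[at_risk, t], penalty=penalty))
        except Exception as exc:
            raise ComponentFitError(f"failure_interval_{t + 1}", exc) from exc
        covs.append(fail_models[-1].cov)

    theta = np.concatenate([cont.beta] + [f.beta for f in fail_models])
    dim = theta.size
    cov_theta = np.zeros((dim, dim))
    off = 0
    for block in covs:
        k = block.shape[0]
        cov_theta[off : off + k, off : off + k] = block
        off += k

    return AugbinFit(
        cont=cont, fail_models=fail_models, theta=theta, cov_theta=cov_theta,
        threshold=data.threshold, quadrature_nodes=config.quadrature_nodes,
        config=config,
    )


def predict_response_probability(fit: AugbinFit, arm: int, baseline: float = 0.0) -> float:
    """Responder probability for a patient standardized to ``arm``."""
    return fit.predict(arm, baseline)


def estimate_effects(
    fit: AugbinFit,
    data: TrialDataset,
    scales: tuple,
    ci_level: Optional[float] = None,
) -> dict:
    """Arm-averaged treatment effects on several scales at once, sharing the
    perturbed-probability evaluations of the delta-method gradient."""
    ci_level = ci_level if ci_level is not None else fit.config.ci_level
    return delta_method_effects(
        fit.pbar_fn(data), fit.theta, fit.cov_theta, tuple(scales), ci_level
    )


def estimate_effect(
    fit: AugbinFit,
    data: TrialDataset,
    scale: Optional[str] = None,
    ci_level: Optional[float] = None,
) -> EffectEstimate:
    """Arm-averaged treatment effect with a delta-method Wald CI."""
    scale = scale or fit.config.scale
    return estimate_effects(fit, data, (scale,), ci_level)[scale]
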