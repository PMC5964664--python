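"""The standard binary comparator: logistic regression on the derived
responder indicator, optionally Firth-penalized, with effects and
delta-method CIs on the same three scales as the joint estimator."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import expit

from .datasets import AnalysisConfig, TrialDataset
from .effects import EffectEstimate, delta_method_effects
from .firth import FirthFit, fit_logistic

__all__ = ["fit_standard_binary", "estimate_effect_binary", "estimate_effects_binary"]


def _design(data: TrialDataset, baseline_adjust: bool) -> np.ndarray:
    cols = [np.ones(data.n_patients), data.arm.astype(float)]
    if baseline_adjust:
        cols.append(data.baseline)
    return np.column_stack(cols)


def fit_standard_binary(data: TrialDataset, config: AnalysisConfig) -> FirthFit:
    """Logistic fit of the responder flag on intercept + arm (+ baseline)."""
    data.require_both_arms(min_per_arm=1)
    X = _design(data, config.baseline_adjust)
    penalty = "firth" if config.firth else "none"
    return fit_logistic(X, data.responder, penalty=penalty)


def estimate_effects_binary(
    fit: FirthFit,
    data: TrialDataset,
    config: AnalysisConfig,
    scales: tuple,
    ci_level: Optional[float] = None,
) -> dict:
    """Standardized effects: every patient predicted under both arms.

    Without extra covariates the log-odds effect and its delta-method SE
    reduce exactly to the arm coefficient and its Wald SE.
    """
    ci_level = ci_level if ci_level is not None else config.ci_level
    X = _design(data, config.baseline_adjust)
    X1 = X.copy()
    X1[:, 1] = 1.0
    X0 = X.copy()
    X0[:, 1] = 0.0

    def pbar_fn(theta):
        return (
            float(np.mean(expit(X1 @ theta))),
            float(np.mean(expit(X0 @ theta))),
        )

    return delta_method_effects(pbar_fn, fit.beta, fit.cov, tuple(scales), ci_level)


def estimate_effect_binary(
    fit: FirthFit,
    data: TrialDataset,
    config: AnalysisConfig,
    scale: Optional[str] = None,
    ci_level: Optional[float] = None,
) -> EffectEstimate:
    """Single-scale wrapper around :func:`estimate_effects_binary`."""
    scale = scale or config.scale
    return estimate_effects_binary(fit, data, config, (scale,), ci_level)[scale]
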