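"""Treatment-effect scales and delta-method confidence intervals.

Every analysis method reduces to a pair of standardized arm-average
response probabilities ``(pbar_1, pbar_0)`` computed from a parameter
vector ``theta`` with covariance ``cov``.  The effect is a smooth function
of the pair; its standard error comes from first-order propagation with a
central-difference gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "EffectEstimate",
    "effect_value",
    "delta_method_effect",
    "delta_method_effects",
    "NULL_VALUE",
]

PROB_CLIP = 1e-10

#: null value of the treatment effect, per scale
NULL_VALUE = {"log_odds": 0.0, "risk_difference": 0.0, "log_risk_ratio": 0.0}


@dataclass
class EffectEstimate:
    """Treatment effect on one scale with a Wald/delta-method CI."""

    scale: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_bar_1: float
    p_bar_0: float
    ci_level: float
    boundary_warning: bool = False

    @property
    def ci_width(self) -> float:
        return self.ci_upper - self.ci_lower

    def excludes_null(self) -> bool:
        """Strict exclusion: a bound exactly at the null counts as covering."""
        null = NULL_VALUE[self.scale]
        return bool(self.ci_lower > null or self.ci_upper < null)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "estimate": self.estimate,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_width": self.ci_width,
            "ci_level": self.ci_level,
            "p_bar_1": self.p_bar_1,
            "p_bar_0": self.p_bar_0,
            "boundary_warning": self.boundary_warning,
        }


def effect_value(p1: float, p0: float, scale: str) -> float:
    if scale == "log_odds":
        return float(np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)))
    if scale == "risk_difference":
        return float(p1 - p0)
    if scale == "log_risk_ratio":
        return float(np.log(p1) - np.log(p0))
    raise ValueError(f"unknown scale {scale!r}")


def delta_method_effects(
    pbar_fn: Callable[[np.ndarray], Tuple[float, float]],
    theta: np.ndarray,
    cov: np.ndarray,
    scales: Tuple[str, ...],
    ci_level: float = 0.95,
) -> dict:
    """Effect estimates with delta-method SEs on one or more scales.

    Parameters
    ----------
    pbar_fn
        Maps a parameter vector to ``(pbar_1, pbar_0)``, the arm-average
        response probabilities with every patient standardized to each arm.
    theta, cov
        Parameter estimate and its covariance (block-diagonal across
        component models for joint fits).

    The gradient uses central differences with step
    ``1e-5 * max(1, |theta_j|)``; the perturbed probability evaluations are
    shared across scales.
    """
    theta = np.asarray(theta, dtype=float)
    p1, p0 = pbar_fn(theta)
    boundary = bool(
        min(p1, p0) <= 2 * PROB_CLIP or max(p1, p0) >= 1 - 2 * PROB_CLIP
    )

    dim = theta.size
    p_up = np.empty((dim, 2))
    p_dn = np.empty((dim, 2))
    steps = np.empty(dim)
    for j in range(dim):
        steps[j] = 1e-5 * max(1.0, abs(theta[j]))
        up = theta.copy()
        up[j] += steps[j]
        dn = theta.copy()
        dn[j] -= steps[j]
        p_up[j] = pbar_fn(up)
        p_dn[j] = pbar_fn(dn)

    z = stats.norm.ppf(0.5 + ci_level / 2)
    out = {}
    for scale in scales:
        est = effect_value(p1, p0, scale)
        grad = np.array(
            [
                (effect_value(*p_up[j], scale) - effect_value(*p_dn[j], scale))
                / (2 * steps[j])
                for j in range(dim)
            ]
        )
        var = float(grad @ cov @ grad)
        se = float(np.sqrt(max(var, 0.0)))
        out[scale] = EffectEstimate(
            scale=scale,
            estimate=est,
            se=se,
            ci_lower=est - z * se,
            ci_upper=est + z * se,
            p_bar_1=p1,
            p_bar_0=p0,
            ci_level=ci_level,
            boundary_warning=boundary,
        )
    return out


def delta_method_effect(
    pbar_fn: Callable[[np.ndarray], Tuple[float, float]],
    theta: np.ndarray,
    cov: np.ndarray,
    scale: str,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Single-scale convenience wrapper around :func:`delta_method_effects`."""
    return delta_method_effects(pbar_fn, theta, cov, (scale,), ci_level)[scale]
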