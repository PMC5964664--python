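"""Synthetic trial generation, calibration to target response rates,
re-sampling / permutation harnesses and the operating-characteristics
engine (power, type I error, coverage, CI width, separation frequency).

The generator mirrors the analysis factorization: correlated normal
continuous outcomes per visit with arm-dependent means, an interval-1
failure indicator depending on arm only, and later failure indicators
conditioned on the preceding continuous outcome.  Final-visit means can be
calibrated by root-finding so the implied marginal responder probabilities
hit requested targets (e.g. 0.470 vs 0.336).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .augmented import estimate_effects, fit_augmented_binary, joint_response_probability
from .datasets import AnalysisConfig, TrialDataset
from .effects import EffectEstimate
from .standard import estimate_effects_binary, fit_standard_binary

__all__ = [
    "GeneratorParams",
    "OperatingCharacteristics",
    "MethodSpec",
    "generate_trial",
    "marginal_response_probability",
    "calibrate_generator",
    "resample_subtrial",
    "permute_labels",
    "analyze_trial",
    "run_operating_characteristics",
    "ci_width_to_sample_size_reduction",
    "separation_frequency",
    "mc_se",
    "default_generator_params",
    "CalibrationError",
]


class CalibrationError(ValueError):
    """Requested marginal response probability is unreachable."""


@dataclass
class GeneratorParams:
    """Parameters of the synthetic-trial generator.

    ``mu[z]`` holds the per-visit means for arm ``z``; ``gamma1`` the
    interval-1 failure logit ``(intercept, arm)``; ``gamma_later[t-2]`` the
    interval-t failure logit ``(intercept, arm, prev-outcome slope)`` for
    t >= 2.
    """

    mu: np.ndarray  # (2, T)
    Sigma: np.ndarray  # (T, T)
    gamma1: np.ndarray  # (2,)
    gamma_later: List[np.ndarray]  # each (3,)
    threshold: float = 20.0
    n_per_arm: int = 100
    quadrature_nodes: int = 40

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.gamma1 = np.asarray(self.gamma1, dtype=float)
        self.gamma_later = [np.asarray(g, dtype=float) for g in self.gamma_later]
        if self.mu.shape[0] != 2:
            raise ValueError("mu must have one row per arm")
        T = self.mu.shape[1]
        if self.Sigma.shape != (T, T):
            raise ValueError("Sigma shape inconsistent with mu")
        if len(self.gamma_later) != T - 1:
            raise ValueError("need one later-interval failure model per visit after the first")
        if np.any(np.linalg.eigvalsh(self.Sigma) <= 0):
            raise ValueError("Sigma must be positive definite")

    @property
    def n_visits(self) -> int:
        return self.mu.shape[1]

    def replace(self, **kw) -> "GeneratorParams":
        return dataclasses.replace(self, **kw)


def default_generator_params(n_per_arm: int = 100, threshold: float = 20.0) -> GeneratorParams:
    """Fixture defaults: sd 30 / correlation 0.6 outcomes, ~8% interval-1
    failure rate, interval-2 failure logit sloping down in the interim
    outcome (~10-12% marginal failure rate)."""
    sd = 30.0
    rho = 0.6
    Sigma = np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])
    return GeneratorParams(
        mu=np.array([[5.0, 10.0], [10.0, 16.0]]),
        Sigma=Sigma,
        gamma1=np.array([-2.442, 0.0]),  # ~8% in both arms
        gamma_later=[np.array([-2.0, 0.0, -0.02])],
        threshold=threshold,
        n_per_arm=n_per_arm,
    )


def generate_trial(params: GeneratorParams, seed: Optional[int] = None) -> TrialDataset:
    """Draw one synthetic trial; byte-identical for a fixed seed."""
    rng = np.random.default_rng(seed)
    T = params.n_visits
    n = 2 * params.n_per_arm
    arm = np.repeat([0, 1], params.n_per_arm)
    y = np.empty((n, T))
    L = np.linalg.cholesky(params.Sigma)
    z_draws = rng.standard_normal((n, T))
    for a in (0, 1):
        sel = arm == a
        y[sel] = params.mu[a] + z_draws[sel] @ L.T
    d = np.zeros((n, T), dtype=int)
    u = rng.random((n, T))
    d[:, 0] = u[:, 0] < expit(params.gamma1[0] + params.gamma1[1] * arm)
    for t in range(1, T):
        g = params.gamma_later[t - 1]
        p_fail = expit(g[0] + g[1] * arm + g[2] * y[:, t - 1])
        d[:, t] = np.where(d[:, t - 1] == 1, 1, (u[:, t] < p_fail).astype(int))
    baseline = rng.normal(50.0, 10.0, size=n)
    pid = np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object)
    return TrialDataset(
        patient_id=pid, arm=arm, baseline=baseline, y=y, d=d,
        threshold=params.threshold,
    )


def marginal_response_probability(params: GeneratorParams, arm: int) -> float:
    """Closed-form (quadrature) marginal responder probability for one arm."""
    eta1 = float(params.gamma1[0] + params.gamma1[1] * arm)
    return joint_response_probability(
        params.mu[arm], params.Sigma, eta1, params.gamma_later, arm,
        params.threshold, params.quadrature_nodes,
    )


def calibrate_generator(
    target_p1: float, target_p0: float, base: GeneratorParams
) -> GeneratorParams:
    """Shift per-arm final-visit means so the implied marginal responder
    probabilities equal the targets (to 1e-6)."""
    for name, target in (("target_p1", target_p1), ("target_p0", target_p0)):
        if not 0.0 < target < 1.0:
            raise CalibrationError(f"{name} must be in (0, 1), got {target}")
    mu = base.mu.copy()
    sd_final = float(np.sqrt(base.Sigma[-1, -1]))
    lo = base.threshold - 15 * sd_final
    hi = base.threshold + 15 * sd_final
    for arm, target in ((0, target_p0), (1, target_p1)):

        def gap(m_final: float) -> float:
            trial_mu = mu.copy()
            trial_mu[arm, -1] = m_final
            p = marginal_response_probability(base.replace(mu=trial_mu), arm)
            return p - target

        if gap(lo) > 0 or gap(hi) < 0:
            raise CalibrationError(
                f"target {target} unreachable for arm {arm} given failure rates"
            )
        mu[arm, -1] = brentq(gap, lo, hi, xtol=1e-10)
    out = base.replace(mu=mu)
    for arm, target in ((0, target_p0), (1, target_p1)):
        if abs(marginal_response_probability(out, arm) - target) > 1e-6:
            raise CalibrationError("calibration did not converge to 1e-6")
    return out


def resample_subtrial(source: TrialDataset, n_total: int, seed: Optional[int] = None) -> TrialDataset:
    """Balanced without-replacement sub-trial of ``n_total`` patients."""
    if n_total % 2 != 0:
        raise ValueError("n_total must be even for a balanced sub-trial")
    half = n_total // 2
    rng = np.random.default_rng(seed)
    idx = []
    for z in (0, 1):
        pool = np.flatnonzero(source.arm == z)
        if len(pool) < half:
            raise ValueError(f"arm {z} has {len(pool)} patients, need {half}")
        idx.append(rng.choice(pool, size=half, replace=False))
    return source.subset(np.concatenate(idx))


def permute_labels(data: TrialDataset, seed: Optional[int] = None) -> TrialDataset:
    """Randomly permute arm labels across patients, outcomes untouched."""
    rng = np.random.default_rng(seed)
    return data.with_arm(rng.permutation(data.arm))


# ---------------------------------------------------------------------------
# analysis method registry


@dataclass(frozen=True)
class MethodSpec:
    """An analysis method for the OC engine.

    ``name`` is ``'binary'`` or ``'augbin'``; ``adjusted`` turns on the
    Firth penalty (both methods) and the MBN sandwich inflation (GEE).
    """

    name: str
    continuous_fitter: str = "GLS"
    adjusted: bool = True

    @property
    def label(self) -> str:
        adj = "adjusted" if self.adjusted else "unadjusted"
        if self.name == "binary":
            return f"binary-{adj}"
        return f"augbin-{self.continuous_fitter.lower()}-{adj}"

    def config(self, threshold: float, scale: str, ci_level: float) -> AnalysisConfig:
        return AnalysisConfig(
            threshold=threshold,
            scale=scale,
            continuous_fitter=self.continuous_fitter,
            firth=self.adjusted,
            mbn=self.adjusted,
            ci_level=ci_level,
        )


def parse_method(label: str) -> MethodSpec:
    """Parse labels like ``binary``, ``augbin-gls``, ``augbin-gee``."""
    parts = label.lower().split("-")
    if parts[0] == "binary":
        return MethodSpec("binary")
    if parts[0] == "augbin":
        fitter = parts[1].upper() if len(parts) > 1 else "GLS"
        return MethodSpec("augbin", continuous_fitter=fitter)
    raise ValueError(f"unknown method label {label!r}")


def analyze_trial(
    data: TrialDataset,
    method: MethodSpec,
    scale: str,
    ci_level: float = 0.95,
    extra_scales: Sequence[str] = (),
) -> Dict[str, EffectEstimate]:
    """Fit one method once and return effects on the primary scale plus any
    extra scales (used to track probability-scale CI widths)."""
    config = method.config(data.threshold, scale, ci_level)
    scales = (scale,) + tuple(s for s in extra_scales if s != scale)
    if method.name == "binary":
        fit = fit_standard_binary(data, config)
        return estimate_effects_binary(fit, data, config, scales)
    fit = fit_augmented_binary(data, config)
    return estimate_effects(fit, data, scales)


# ---------------------------------------------------------------------------
# operating characteristics


@dataclass
class OperatingCharacteristics:
    """Per-sample-size summary of one method's simulation behaviour."""

    n_total: int
    mode: str
    power: Optional[float]
    type1: Optional[float]
    coverage: Optional[float]
    mean_ci_width: float
    median_ci_width: float
    separation_freq: float
    n_reps: int
    n_errors: int
    mc_se: float
    mean_estimate: float
    scale: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def mc_se(p: float, n_reps: int) -> float:
    """Monte Carlo standard error of an estimated proportion."""
    return float(np.sqrt(p * (1.0 - p) / n_reps))


def ci_width_to_sample_size_reduction(width_reduction: float) -> float:
    """Convert a fractional CI-width reduction to the implied reduction in
    required sample size, using CI width proportional to 1/sqrt(n):
    ``1 - (1 - w)**2``."""
    if not 0.0 <= width_reduction < 1.0:
        raise ValueError(f"width_reduction must be in [0, 1), got {width_reduction}")
    return 1.0 - (1.0 - width_reduction) ** 2


def separation_frequency(ci_widths: Sequence[float], threshold: float = 1.0) -> float:
    """Proportion of probability-scale CI widths strictly above ``threshold``
    (the extreme-variance / perfect-separation diagnostic)."""
    widths = np.asarray(list(ci_widths), dtype=float)
    if widths.size == 0:
        raise ValueError("separation_frequency of an empty width list is undefined")
    if (widths < 0).any():
        raise ValueError("CI widths must be non-negative")
    return float(np.mean(widths > threshold))


def run_operating_characteristics(
    methods: Union[MethodSpec, Sequence[MethodSpec]],
    source: Union[GeneratorParams, TrialDataset],
    n_grid: Sequence[int],
    n_reps: int,
    alpha: float = 0.05,
    mode: str = "power",
    scale: str = "log_odds",
    seed: int = 0,
) -> Dict[str, Dict[int, OperatingCharacteristics]]:
    """Estimate operating characteristics over a sample-size grid.

    Every method is applied to the *same* replicate datasets, which makes
    paired comparisons (power ordering, width reductions) far less noisy
    than independent runs.  Replicates on which a method errors out are
    excluded from that method's proportions and counted in ``n_errors``.

    A method may also be any callable ``f(data, scale, ci_level,
    extra_scales) -> dict[scale, EffectEstimate]`` carrying a ``label``
    attribute (useful for stubbing in tests).

    With ``mode='type1'`` arm labels are permuted within each replicate to
    break the treatment-outcome association; ``coverage`` is then reported
    as the complement of the rejection rate.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for meaningful proportions")
    if mode not in ("power", "type1"):
        raise ValueError("mode must be 'power' or 'type1'")
    if not isinstance(methods, (list, tuple)):
        methods = [methods]
    ci_level = 1.0 - alpha
    track_scales = ("risk_difference",) if scale != "risk_difference" else ()

    results: Dict[str, Dict[int, OperatingCharacteristics]] = {m.label: {} for m in methods}
    root = np.random.SeedSequence(seed)
    for n_total in n_grid:
        child_seqs = root.spawn(n_reps)
        rej = {m.label: [] for m in methods}
        widths = {m.label: [] for m in methods}
        rd_widths = {m.label: [] for m in methods}
        ests = {m.label: [] for m in methods}
        errors = {m.label: 0 for m in methods}
        for seq in child_seqs:
            s_data, s_perm = [int(s.generate_state(1)[0]) for s in seq.spawn(2)]
            if isinstance(source, GeneratorParams):
                data = generate_trial(source.replace(n_per_arm=n_total // 2), seed=s_data)
            else:
                data = resample_subtrial(source, n_total, seed=s_data)
            if mode == "type1":
                data = permute_labels(data, seed=s_perm)
            for m in methods:
                try:
                    if isinstance(m, MethodSpec):
                        effs = analyze_trial(data, m, scale, ci_level, track_scales)
                    else:
                        effs = m(data, scale, ci_level, track_scales)
                except Exception:
                    errors[m.label] += 1
                    continue
                primary = effs[scale]
                rej[m.label].append(primary.excludes_null())
                widths[m.label].append(primary.ci_width)
                rd_widths[m.label].append(effs.get("risk_difference", primary).ci_width)
                ests[m.label].append(primary.estimate)
        for m in methods:
            ok = len(rej[m.label])
            if ok == 0:
                raise RuntimeError(f"all replicates failed for {m.label} at n={n_total}")
            p_rej = float(np.mean(rej[m.label]))
            results[m.label][n_total] = OperatingCharacteristics(
                n_total=n_total,
                mode=mode,
                power=p_rej if mode == "power" else None,
                type1=p_rej if mode == "type1" else None,
                coverage=(1.0 - p_rej) if mode == "type1" else None,
                mean_ci_width=float(np.mean(widths[m.label])),
                median_ci_width=float(np.median(widths[m.label])),
                separation_freq=separation_frequency(rd_widths[m.label]),
                n_reps=ok,
                n_errors=errors[m.label],
                mc_se=mc_se(p_rej, ok),
                mean_estimate=float(np.mean(ests[m.label])),
                scale=scale,
            )
    return results
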