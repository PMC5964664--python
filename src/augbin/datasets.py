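"""Trial data containers, validation, responder derivation and CSV / YAML I/O.

A trial is stored patient-per-row: arm label, baseline score, a continuous
percent-improvement outcome at each of ``T`` scheduled visits (missing
allowed, stored as NaN) and ``T`` binary failure indicators (rescue
medication / restricted treatment / withdrawal).  The failure state is
absorbing: once a patient fails in interval ``t`` the indicator stays 1 for
every later interval.

A patient is a *responder* iff the final-visit continuous outcome is
observed, reaches the response threshold, and no failure occurred in any
interval.  A missing final-visit outcome or any failure forces
non-response.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialDataset",
    "AnalysisConfig",
    "TrialDataFormatError",
    "TrialDataValidationError",
    "derive_responder",
    "read_trial_csv",
    "write_trial_csv",
]


class TrialDataFormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class TrialDataValidationError(ValueError):
    """Raised when trial data violate a structural invariant."""


VALID_SCALES = ("log_odds", "risk_difference", "log_risk_ratio")
VALID_FITTERS = ("GLS", "GEE")


@dataclass
class AnalysisConfig:
    """Settings shared by all analysis entry points.

    Parameters
    ----------
    threshold
        Response cut-off applied to the final-visit continuous outcome
        (e.g. 20, 50 or 70 for percent-improvement endpoints).
    scale
        Treatment-effect scale: ``log_odds``, ``risk_difference`` or
        ``log_risk_ratio``.
    continuous_fitter
        ``GLS`` (normal likelihood) or ``GEE`` for the repeated-measures
        continuous component.
    firth
        Use Firth penalized likelihood for all logistic component models.
    mbn
        Apply the small-sample sandwich-variance inflation to GEE fits.
    baseline_adjust
        Include the baseline score in the mean model of the continuous
        component and in the responder / failure logistic models.
    ci_level
        Two-sided confidence level, in (0, 1).
    quadrature_nodes
        Gauss-Hermite nodes used for response-probability integrals.
    """

    threshold: float = 20.0
    scale: str = "log_odds"
    continuous_fitter: str = "GLS"
    firth: bool = True
    mbn: bool = True
    baseline_adjust: bool = False
    ci_level: float = 0.95
    quadrature_nodes: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.quadrature_nodes < 8:
            raise ValueError("quadrature_nodes must be >= 8")
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.continuous_fitter not in VALID_FITTERS:
            raise ValueError(
                f"continuous_fitter must be one of {VALID_FITTERS}, "
                f"got {self.continuous_fitter!r}"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TrialDataFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def derive_responder(y_final: float, d: Sequence[int], c: float) -> int:
    """Return 1 iff ``y_final`` is observed, ``>= c`` and no failure occurred.

    Missing (NaN / None) final outcomes are non-responders by definition.
    """
    if y_final is None or (isinstance(y_final, float) and np.isnan(y_final)):
        return 0
    if any(int(dt) != 0 for dt in d):
        return 0
    return int(float(y_final) >= c)


@dataclass
class TrialDataset:
    """Patient-level composite-endpoint trial data.

    Attributes
    ----------
    patient_id : ndarray of object
        Opaque identifiers, one per patient.
    arm : ndarray of int
        0 = control, 1 = treatment.
    baseline : ndarray of float
        Baseline score (NaN allowed when unused).
    y : ndarray, shape (n, T)
        Continuous outcomes at the T scheduled visits; NaN = missing.
    d : ndarray, shape (n, T)
        Absorbing binary failure indicators per interval.
    threshold : float
        Response cut-off on the final-visit outcome.
    """

    patient_id: np.ndarray
    arm: np.ndarray
    baseline: np.ndarray
    y: np.ndarray
    d: np.ndarray
    threshold: float
    responder: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.patient_id = np.asarray(self.patient_id, dtype=object)
        self.arm = np.asarray(self.arm, dtype=int)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.d = np.atleast_2d(np.asarray(self.d, dtype=int))
        n = len(self.patient_id)
        if not (len(self.arm) == len(self.baseline) == self.y.shape[0] == self.d.shape[0] == n):
            raise TrialDataValidationError("field lengths disagree")
        if self.y.shape != self.d.shape:
            raise TrialDataValidationError("y and d must have the same shape")
        bad_arm = ~np.isin(self.arm, (0, 1))
        if bad_arm.any():
            who = self.patient_id[bad_arm][0]
            raise TrialDataValidationError(f"arm outside {{0,1}} for patient {who!r}")
        if (np.diff(self.d, axis=1) < 0).any():
            who = self.patient_id[(np.diff(self.d, axis=1) < 0).any(axis=1)][0]
            raise TrialDataValidationError(
                f"failure indicators not monotone for patient {who!r}"
            )
        if not np.isin(self.d, (0, 1)).all():
            raise TrialDataValidationError("failure indicators must be 0/1")
        self.responder = self._derive_responders()

    def _derive_responders(self) -> np.ndarray:
        y_final = self.y[:, -1]
        ok = np.isfinite(y_final) & (y_final >= self.threshold) & (self.d == 0).all(axis=1)
        return ok.astype(int)

    @property
    def n_patients(self) -> int:
        return len(self.patient_id)

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    def require_both_arms(self, min_per_arm: int = 1) -> None:
        for z in (0, 1):
            if (self.arm == z).sum() < min_per_arm:
                raise TrialDataValidationError(
                    f"arm {z} has fewer than {min_per_arm} patients"
                )

    def subset(self, idx: np.ndarray) -> "TrialDataset":
        """Row-subset (or re-ordered) copy."""
        return TrialDataset(
            patient_id=self.patient_id[idx],
            arm=self.arm[idx],
            baseline=self.baseline[idx],
            y=self.y[idx],
            d=self.d[idx],
            threshold=self.threshold,
        )

    def with_arm(self, arm: np.ndarray) -> "TrialDataset":
        """Copy with replaced arm labels (used by permutation nulls)."""
        return TrialDataset(
            patient_id=self.patient_id.copy(),
            arm=np.asarray(arm, dtype=int),
            baseline=self.baseline.copy(),
            y=self.y.copy(),
            d=self.d.copy(),
            threshold=self.threshold,
        )

    def to_frame(self) -> pd.DataFrame:
        T = self.n_visits
        out = {"patient_id": self.patient_id, "arm": self.arm, "baseline": self.baseline}
        for t in range(T):
            out[f"y_{t + 1}"] = self.y[:, t]
        for t in range(T):
            out[f"d_{t + 1}"] = self.d[:, t]
        return pd.DataFrame(out)


def read_trial_csv(path: str, config: AnalysisConfig) -> TrialDataset:
    """Read a patient-per-row CSV into a validated :class:`TrialDataset`.

    Expected columns: ``patient_id, arm, baseline, y_1..y_T, d_1..d_T``.
    Empty cells are missing values.  Row order is preserved.
    """
    df = pd.read_csv(path)
    for col in ("patient_id", "arm", "baseline"):
        if col not in df.columns:
            raise TrialDataFormatError(f"missing required column {col!r}")
    y_cols = sorted(
        (c for c in df.columns if c.startswith("y_") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    d_cols = sorted(
        (c for c in df.columns if c.startswith("d_") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    if not y_cols or not d_cols:
        raise TrialDataFormatError("no y_t / d_t outcome columns found")
    if len(y_cols) != len(d_cols):
        raise TrialDataFormatError("y_t and d_t column counts disagree")
    expected_y = [f"y_{t}" for t in range(1, len(y_cols) + 1)]
    expected_d = [f"d_{t}" for t in range(1, len(d_cols) + 1)]
    if y_cols != expected_y or d_cols != expected_d:
        raise TrialDataFormatError("outcome columns must be consecutively numbered from 1")
    d = df[d_cols].to_numpy()
    if np.isnan(d.astype(float)).any():
        raise TrialDataFormatError("failure indicators may not be missing")
    return TrialDataset(
        patient_id=df["patient_id"].to_numpy(dtype=object),
        arm=df["arm"].to_numpy(),
        baseline=df["baseline"].to_numpy(dtype=float),
        y=df[y_cols].to_numpy(dtype=float),
        d=d.astype(int),
        threshold=config.threshold,
    )


def write_trial_csv(data: TrialDataset, path: str) -> None:
    """Write a dataset in the layout accepted by :func:`read_trial_csv`."""
    data.to_frame().to_csv(path, index=False)
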