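"""Comparison reports: pairwise CI-width reductions between methods, the
implied required-sample-size reductions, and JSON / aligned-text rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict

from .simulate import OperatingCharacteristics, ci_width_to_sample_size_reduction

__all__ = ["ComparisonReport", "build_comparison", "oc_results_to_dict"]

SCHEMA_VERSION = 1


@dataclass
class ComparisonReport:
    """Width comparison of method B against reference method A.

    ``width_reduction`` is ``1 - mean_width_b / mean_width_a`` per grid
    point; the overall figure averages over the grid.  Sample-size
    reductions are always recomputed from the width fields, so the two are
    internally consistent by construction.
    """

    label_a: str
    label_b: str
    mode: str
    scale: str
    per_n: Dict[int, dict]
    avg_width_reduction: float
    metadata: dict = field(default_factory=dict)

    @property
    def avg_sample_size_reduction(self) -> float:
        return ci_width_to_sample_size_reduction(max(self.avg_width_reduction, 0.0))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "label_a": self.label_a,
            "label_b": self.label_b,
            "mode": self.mode,
            "scale": self.scale,
            "per_n": {str(n): v for n, v in self.per_n.items()},
            "avg_width_reduction": self.avg_width_reduction,
            "avg_sample_size_reduction": self.avg_sample_size_reduction,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, raw: dict) -> "ComparisonReport":
        return cls(
            label_a=raw["label_a"],
            label_b=raw["label_b"],
            mode=raw["mode"],
            scale=raw["scale"],
            per_n={int(n): v for n, v in raw["per_n"].items()},
            avg_width_reduction=raw["avg_width_reduction"],
            metadata=raw.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls.from_dict(json.loads(text))

    def render_text(self) -> str:
        """Aligned-text table; a pure rendering of the JSON content."""
        lines = [
            f"Comparison: {self.label_a} vs {self.label_b} "
            f"({self.mode}, {self.scale} scale)",
            f"{'n':>6} {'width A':>10} {'width B':>10} "
            f"{'width red. (%)':>15} {'n red. (%)':>12}",
        ]
        for n in sorted(self.per_n):
            row = self.per_n[n]
            lines.append(
                f"{n:>6} {row['mean_width_a']:>10.4f} {row['mean_width_b']:>10.4f} "
                f"{100 * row['width_reduction']:>15.1f} "
                f"{100 * row['sample_size_reduction']:>12.1f}"
            )
        lines.append(
            f"Average width reduction: {100 * self.avg_width_reduction:.1f}%  "
            f"-> required sample size reduction: "
            f"{100 * self.avg_sample_size_reduction:.1f}%"
        )
        return "\n".join(lines)


def build_comparison(
    oc_a: Dict[int, OperatingCharacteristics],
    oc_b: Dict[int, OperatingCharacteristics],
    label_a: str = "A",
    label_b: str = "B",
    metadata: dict | None = None,
) -> ComparisonReport:
    """Pairwise mean-CI-width comparison over a shared sample-size grid."""
    if sorted(oc_a) != sorted(oc_b):
        raise ValueError(f"sample-size grids differ: {sorted(oc_a)} vs {sorted(oc_b)}")
    modes = {oc.mode for oc in oc_a.values()} | {oc.mode for oc in oc_b.values()}
    if len(modes) != 1:
        raise ValueError(f"mixed modes in comparison: {modes}")
    scales = {oc.scale for oc in oc_a.values()} | {oc.scale for oc in oc_b.values()}
    if len(scales) != 1:
        raise ValueError(f"mixed scales in comparison: {scales}")

    per_n = {}
    reductions = []
    for n in sorted(oc_a):
        wa, wb = oc_a[n].mean_ci_width, oc_b[n].mean_ci_width
        red = 1.0 - wb / wa
        per_n[n] = {
            "mean_width_a": wa,
            "mean_width_b": wb,
            "width_reduction": red,
            "sample_size_reduction": ci_width_to_sample_size_reduction(max(red, 0.0)),
        }
        reductions.append(red)
    return ComparisonReport(
        label_a=label_a,
        label_b=label_b,
        mode=modes.pop(),
        scale=scales.pop(),
        per_n=per_n,
        avg_width_reduction=float(sum(reductions) / len(reductions)),
        metadata=metadata or {},
    )


def oc_results_to_dict(results: Dict[str, Dict[int, OperatingCharacteristics]]) -> dict:
    """Serialize an OC run (method label -> n -> summary) for JSON output."""
    return {
        "schema_version": SCHEMA_VERSION,
        "methods": {
            label: {str(n): oc.to_dict() for n, oc in per_n.items()}
            for label, per_n in results.items()
        },
    }
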