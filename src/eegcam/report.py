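"""Shared performance-report container."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np


@dataclass
class PerformanceReport:
    """Accuracy metrics for one experiment.

    ``accuracy`` is pattern-level (fraction of probes whose recalled state is
    nearest its own source/class), ``bit_accuracy`` the mean fraction of
    final-state bits matching the source pattern where that is meaningful.
    ``significance`` is a p-value from an exact binomial (or permutation)
    null at chance level 0.5.
    """

    accuracy: float
    bit_accuracy: float | None = None
    per_repeat: list[float] = field(default_factory=list)
    n_train: int | None = None
    n_test: int | None = None
    seed: int | None = None
    significance: float | None = None
    notes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("accuracy", self.accuracy),
                        ("bit_accuracy", self.bit_accuracy)):
            if v is not None and not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def mean_error(self) -> float:
        """1 − bit-level performance (falls back to pattern level)."""
        base = self.accuracy if self.bit_accuracy is None else self.bit_accuracy
        return 1.0 - base

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["mean_error"] = self.mean_error
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in d.items()}

    def summary(self) -> str:
        lines = [f"accuracy: {self.accuracy:.1%}"]
        if self.bit_accuracy is not None:
            lines.append(f"bit-level performance: {self.bit_accuracy:.1%}"
                         f"  (mean error {self.mean_error:.3f})")
        if self.per_repeat:
            lines.append("per repeat: " + ", ".join(f"{a:.1%}" for a in self.per_repeat))
        if self.n_train is not None:
            lines.append(f"train/test sizes: {self.n_train}/{self.n_test}")
        if self.significance is not None:
            lines.append(f"p (binomial vs chance): {self.significance:.2e}")
        for k, v in self.notes.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)
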