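"""Error-report container shared by the registration and phantom experiments."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ErrorReport"]


@dataclass
class ErrorReport:
    """Mean +/- SD of a Euclidean error metric over replicates (all in mm).

    ``values`` holds the per-replicate (or per-pair) errors so the summary
    statistics can always be recomputed; ``config`` echoes the experiment
    configuration, including the seed for stochastic studies.
    """

    metric: str
    values: np.ndarray
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("an ErrorReport needs at least one value")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0

    @property
    def n(self) -> int:
        return int(self.values.size)

    def summary(self) -> str:
        return f"{self.metric}: {self.mean:.3f} +/- {self.sd:.3f} mm (n={self.n})"

    def to_dict(self) -> dict[str, Any]:
        return {
            "metric": self.metric,
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "n": self.n,
            "values_mm": self.values.tolist(),
            "config": self.config,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
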