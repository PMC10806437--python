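"""Finite-support probability mass functions over the non-negative integers.

Burst-size and reproduction-number distributions have unbounded support, so
they are stored truncated, with the mass beyond the truncation point
recorded in ``tail_mass``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DiscretePMF", "TruncationError"]

_NORM_TOL = 1e-9


class TruncationError(RuntimeError):
    """Raised when a p.m.f. cannot be truncated to the requested tail mass."""


@dataclass
class DiscretePMF:
    """Probabilities ``probs[v]`` for integer values v = 0, 1, ..., len-1.

    ``sum(probs) + tail_mass`` must equal 1 within 1e-9.
    """

    probs: np.ndarray
    tail_mass: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size == 0:
            raise ValueError("probs must be a non-empty 1-d array")
        if np.any(self.probs < -1e-15) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        total = self.probs.sum() + self.tail_mass
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"p.m.f. not normalised: total mass {total!r}")

    # -- summaries ---------------------------------------------------------
    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    @property
    def max_value(self) -> int:
        return self.probs.size - 1

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def var(self) -> float:
        m = self.mean()
        return float((self.support.astype(float) ** 2) @ self.probs - m * m)

    def p0(self) -> float:
        """Probability of the value zero."""
        return float(self.probs[0])

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probs)

    def pgf(self, s: float) -> float:
        """Evaluate the generating function sum_v probs[v] * s**v."""
        return float(np.polynomial.polynomial.polyval(s, self.probs))

    # -- comparisons -------------------------------------------------------
    def aligned_with(self, other: "DiscretePMF") -> tuple[np.ndarray, np.ndarray]:
        """Zero-pad the shorter support so both arrays share a length."""
        n = max(self.probs.size, other.probs.size)
        a = np.zeros(n)
        b = np.zeros(n)
        a[: self.probs.size] = self.probs
        b[: other.probs.size] = other.probs
        return a, b

    def tv_distance(self, other: "DiscretePMF") -> float:
        a, b = self.aligned_with(other)
        return 0.5 * float(np.abs(a - b).sum())

    # -- export ------------------------------------------------------------
    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"value": self.support, "probability": self.probs})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = Path(path).with_suffix(Path(path).suffix + ".json")
        meta.write_text(
            json.dumps({"label": self.label, "tail_mass": self.tail_mass}, indent=1)
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "label": self.label,
                    "tail_mass": self.tail_mass,
                    "probs": self.probs.tolist(),
                },
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretePMF":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["probs"]), d.get("tail_mass", 0.0), d.get("label", ""))

    @classmethod
    def from_samples(cls, samples, label: str = "") -> "DiscretePMF":
        """Empirical p.m.f. of a sample of non-negative integers."""
        samples = np.asarray(samples, dtype=np.int64)
        counts = np.bincount(samples)
        return cls(counts / counts.sum(), 0.0, label)

    @classmethod
    def point_mass(cls, value: int, label: str = "") -> "DiscretePMF":
        probs = np.zeros(value + 1)
        probs[value] = 1.0
        return cls(probs, 0.0, label)
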