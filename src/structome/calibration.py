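"""Exponential calibration between ribosome density and doubling time.

Across microbes profiled by serial-section ribosome enumeration, the
population doubling time shortens roughly exponentially with the
cytoplasmic ribosome density.  The calibration model is

    y = a * exp(-b * x)

with ``x`` the ribosome density per 0.1 fl cytoplasm and ``y`` the doubling
time in minutes; ``a`` is the extrapolated doubling time at zero density
and ``b`` the decay rate per density unit.  The default model ships with
the published constants a = 4998.5 min, b = 0.002, and can be re-fitted
from user-supplied (density, doubling-time) pairs by log-linear least
squares.  The inverse maps an observed doubling time back to a density, or
— the intended use — a density measured in an uncultivable organism to a
predicted doubling time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationModel",
    "DEFAULT_MODEL",
    "predict_doubling_time",
    "fit_exponential",
    "invert_doubling",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Parameters of the exponential density→doubling-time model."""

    a: float  # doubling time (min) at zero density
    b: float  # decay rate per (ribosomes / 0.1 fl)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"b must be > 0, got {self.b}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"a": self.a, "b": self.b, "provenance": self.provenance},
            indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(a=float(d["a"]), b=float(d["b"]),
                   provenance=str(d.get("provenance", "")))


#: Published calibration constants (doubling time in minutes).
DEFAULT_MODEL = CalibrationModel(
    a=4998.5, b=0.002,
    provenance="default exponential ribosome-density/doubling-time calibration",
)


def predict_doubling_time(density: float, model: CalibrationModel = DEFAULT_MODEL,
                          ) -> float:
    """Doubling time in minutes at the given ribosome density (per 0.1 fl)."""
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    return model.a * math.exp(-model.b * density)


def fit_exponential(pairs: Sequence[tuple[float, float]],
                    provenance: str = "log-linear least-squares fit",
                    ) -> CalibrationModel:
    """Fit the exponential model by least squares of log doubling time on density.

    Requires at least two pairs with positive doubling times and at least
    two distinct densities; with exactly two points the curve interpolates
    both.  Raises when the fitted trend is not decreasing (b <= 0), since a
    doubling time that grows with ribosome density has no meaning in this
    model.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("fit requires >= 2 (density, doubling_time) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.any(y <= 0):
        raise ValueError("doubling times must be > 0")
    if np.unique(x).size < 2:
        raise ValueError("fit requires at least two distinct densities")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    a, b = float(np.exp(intercept)), float(-slope)
    if b <= 0:
        raise ValueError(
            f"fitted decay rate is not positive (b = {b:.4g}); the data do "
            "not show doubling time decreasing with density"
        )
    return CalibrationModel(a=a, b=b, provenance=provenance)


def invert_doubling(doubling_time: float, model: CalibrationModel = DEFAULT_MODEL,
                    ) -> float:
    """Ribosome density (per 0.1 fl) implied by a doubling time in minutes.

    Defined for ``0 < doubling_time <= a``; longer times would imply a
    negative density.
    """
    if not doubling_time > 0:
        raise ValueError(f"doubling_time must be > 0, got {doubling_time}")
    if doubling_time > model.a:
        raise ValueError(
            f"doubling_time {doubling_time} exceeds the zero-density limit "
            f"a = {model.a}"
        )
    return math.log(model.a / doubling_time) / model.b
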