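"""Piecewise-linear response curves.

Most environmental response functions in the model (photosynthesis
factors, turnover modifiers, target-ratio modifiers) are defined as
piecewise-linear tables so that every anchor is a configuration entry.
Values outside the tabulated x-range are held at the end-point y values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class PiecewiseLinear:
    """A monotone-x piecewise-linear function y(x).

    Parameters
    ----------
    x, y : sequences of equal length (>= 2 points, or 1 for a constant).
        x must be strictly increasing.
    """

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        x = tuple(float(v) for v in x)
        y = tuple(float(v) for v in y)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if len(x) == 0:
            raise ValueError("curve needs at least one point")
        if any(b <= a for a, b in zip(x, x[1:])):
            raise ValueError(f"curve x values must be strictly increasing: {x}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __call__(self, v: float) -> float:
        return float(np.interp(v, self.x, self.y))

    @classmethod
    def from_pairs(cls, pairs: Sequence[Sequence[float]]) -> "PiecewiseLinear":
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        return cls(xs, ys)

    def to_pairs(self) -> list[list[float]]:
        return [[a, b] for a, b in zip(self.x, self.y)]


def curve_field(pairs: Sequence[Sequence[float]]):
    """Dataclass default factory for a PiecewiseLinear curve."""
    frozen = tuple(tuple(p) for p in pairs)
    return field(default_factory=lambda: PiecewiseLinear.from_pairs(frozen))
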