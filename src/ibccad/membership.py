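"""Trapezoidal membership functions, Type-1 and interval Type-2.

Linguistic terms Low / Medium / High over each asymmetry ratio are modeled
as trapezoids (a, b, c, d): zero outside [a, d], one on the core [b, c],
linear on the shoulders.  Open shoulders use infinite breakpoints
(a = b = -inf for a left shoulder, c = d = +inf for a right one).

An interval Type-2 term carries a lower and an upper trapezoid; the region
between them is the footprint of uncertainty (FoU), with a uniform secondary
grade.  Here the FoU is produced by expanding the base trapezoid's
breakpoints outward by a width ``delta`` (upper bound) and shrinking them
inward by the same width (lower bound), so ``delta = 0`` collapses exactly
to the Type-1 term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

__all__ = ["TrapezoidMF", "IT2TrapezoidMF"]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoid (a <= b <= c <= d); breakpoints may be infinite."""

    a: float
    b: float
    c: float
    d: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(
                f"trapezoid breakpoints must be non-decreasing, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )
        if not (np.isfinite(self.b) or self.b == -np.inf):
            raise ValueError("b must be finite or -inf")
        if not (np.isfinite(self.c) or self.c == np.inf):
            raise ValueError("c must be finite or +inf")

    def degree(self, x: ArrayLike) -> ArrayLike:
        """Piecewise-linear membership degree in [0, 1]; exact at breakpoints."""
        x = np.asarray(x, dtype=float)
        y = np.where((x >= self.b) & (x <= self.c), 1.0, 0.0)
        if np.isfinite(self.a) and np.isfinite(self.b) and self.b > self.a:
            rising = (x > self.a) & (x < self.b)
            y = np.where(rising, (x - self.a) / (self.b - self.a), y)
        if np.isfinite(self.c) and np.isfinite(self.d) and self.d > self.c:
            falling = (x > self.c) & (x < self.d)
            y = np.where(falling, (self.d - x) / (self.d - self.c), y)
        return float(y) if y.ndim == 0 else y

    def expanded(self, delta: float) -> "TrapezoidMF":
        """Widen by ``delta`` on both sides (infinite breakpoints unchanged)."""
        if delta < 0:
            raise ValueError("FoU width must be >= 0")
        shift = lambda v, s: v + s if np.isfinite(v) else v
        return TrapezoidMF(
            shift(self.a, -delta),
            shift(self.b, -delta),
            shift(self.c, delta),
            shift(self.d, delta),
            self.label,
        )

    def shrunk(self, delta: float) -> "TrapezoidMF":
        """Narrow by ``delta``; a collapsing core degenerates to its midpoint."""
        if delta < 0:
            raise ValueError("FoU width must be >= 0")
        shift = lambda v, s: v + s if np.isfinite(v) else v
        a, b = shift(self.a, delta), shift(self.b, delta)
        c, d = shift(self.c, -delta), shift(self.d, -delta)
        if b > c:  # core collapsed: pinch to the old core midpoint
            mid = (self.b + self.c) / 2.0
            b = c = mid
        a, d = min(a, b), max(d, c)
        return TrapezoidMF(a, b, c, d, self.label)


@dataclass(frozen=True)
class IT2TrapezoidMF:
    """Interval Type-2 term: lower and upper trapezoids sharing a label."""

    lower: TrapezoidMF
    upper: TrapezoidMF
    label: str = ""

    @classmethod
    def from_base(cls, base: TrapezoidMF, delta: float) -> "IT2TrapezoidMF":
        """Symmetric FoU of width ``delta`` around a Type-1 trapezoid."""
        return cls(lower=base.shrunk(delta), upper=base.expanded(delta),
                   label=base.label)

    def degree(self, x: ArrayLike) -> Tuple[ArrayLike, ArrayLike]:
        """(lower, upper) membership degrees; lower <= upper everywhere."""
        lo = self.lower.degree(x)
        up = self.upper.degree(x)
        return np.minimum(lo, up), np.maximum(lo, up)
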