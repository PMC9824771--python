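"""Interval Type-2 Mamdani classifier with Karnik-Mendel type reduction.

The Type-2 system shares the Type-1 rule base and singleton consequents but
fuzzifies each feature with interval terms: every membership degree is an
interval [lower, upper] bounded by two trapezoids whose gap — the footprint
of uncertainty (FoU) — absorbs the uncertainty of placing crisp membership
boundaries on a 14-case evidence base.  Rules fire as intervals
(min of lower degrees, min of upper degrees); the fired intervals are
type-reduced to an output interval [y_l, y_r] with the Karnik-Mendel
procedure, and the crisp likelihood is the interval midpoint, thresholded
at 0.5 like the Type-1 system.

The FoU widths are per-feature and are found by :func:`calibrate_fou`, a
deterministic grid search that returns the smallest symmetric expansion of
the Type-1 trapezoids that classifies the whole reference cohort correctly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureVector
from .fuzzy_type1 import (
    FEATURES,
    FVLike,
    FuzzyRule,
    Prediction,
    Type1Config,
    _fv_values,
)
from .membership import IT2TrapezoidMF

__all__ = [
    "Type2Config",
    "CalibrationError",
    "make_type2_config",
    "it2_membership",
    "fire_rules_it2",
    "type_reduce",
    "classify_t2",
    "calibrate_fou",
]

log = logging.getLogger(__name__)


@dataclass
class Type2Config:
    """Interval Type-2 membership sets plus the shared decision parameters."""

    mfs: Dict[str, Dict[str, IT2TrapezoidMF]]
    rules: Tuple[FuzzyRule, ...]
    threshold: float = 0.5
    firing_floor: float = 1e-9
    fallback: float = 0.0
    fou_widths: Optional[Dict[str, float]] = None  # provenance of the FoU

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.firing_floor <= 0:
            raise ValueError("firing floor must be > 0")
        for feat in FEATURES:
            if feat not in self.mfs:
                raise ValueError(f"missing membership functions for {feat}")


def make_type2_config(
    base: Type1Config, fou_widths: Dict[str, float]
) -> Type2Config:
    """Build an interval Type-2 config by widening a Type-1 config.

    Each feature's trapezoids are expanded outward by ``fou_widths[feat]``
    for the upper bound and shrunk inward by the same amount for the lower
    bound; width 0 leaves the term exactly Type-1.
    """
    mfs = {
        feat: {
            lab: IT2TrapezoidMF.from_base(mf, float(fou_widths.get(feat, 0.0)))
            for lab, mf in terms.items()
        }
        for feat, terms in base.mfs.items()
    }
    return Type2Config(
        mfs=mfs,
        rules=base.rules,
        threshold=base.threshold,
        firing_floor=base.firing_floor,
        fallback=base.fallback,
        fou_widths={f: float(fou_widths.get(f, 0.0)) for f in FEATURES},
    )


def it2_membership(x: float, mf: IT2TrapezoidMF) -> Tuple[float, float]:
    """Interval membership degree [lower, upper] of one feature value."""
    lo, up = mf.degree(x)
    return float(lo), float(up)


def fire_rules_it2(fv: FVLike, config: Type2Config) -> np.ndarray:
    """Per-rule firing intervals, shape (n_rules, 2) with columns (w_, w^).

    The lower firing strength is the min over the antecedents' lower
    degrees; the upper strength the min over their upper degrees.
    """
    vals = _fv_values(fv)
    out = np.empty((len(config.rules), 2))
    for i, rule in enumerate(config.rules):
        intervals = [
            it2_membership(x, config.mfs[feat][lab])
            for feat, lab, x in zip(FEATURES, rule.antecedents, vals)
        ]
        out[i, 0] = min(lo for lo, _ in intervals)
        out[i, 1] = min(up for _, up in intervals)
    return out


def _switch_scan(
    c: np.ndarray, wl: np.ndarray, wu: np.ndarray, minimize: bool
) -> float:
    """Exact optimum of sum(w c)/sum(w) over switch-point weight patterns.

    ``c`` must be sorted ascending.  Used as a robust fallback when the
    Karnik-Mendel iteration hits a zero denominator.
    """
    n = len(c)
    best = np.inf if minimize else -np.inf
    for k in range(-1, n):
        if minimize:  # upper weights on small consequents
            w = np.concatenate([wu[: k + 1], wl[k + 1 :]])
        else:
            w = np.concatenate([wl[: k + 1], wu[k + 1 :]])
        s = w.sum()
        if s <= 0:
            continue
        y = float(w @ c / s)
        best = min(best, y) if minimize else max(best, y)
    return best


def _km_endpoint(
    c: np.ndarray, wl: np.ndarray, wu: np.ndarray, minimize: bool
) -> float:
    """Karnik-Mendel iteration for one endpoint (c sorted ascending)."""
    w = (wl + wu) / 2.0
    if w.sum() <= 0:  # pragma: no cover - guarded by caller
        w = wu.copy()
    y = float(w @ c / w.sum())
    for _ in range(100):
        if minimize:
            w = np.where(c <= y, wu, wl)
        else:
            w = np.where(c > y, wu, wl)
        s = w.sum()
        if s <= 0:
            return _switch_scan(c, wl, wu, minimize)
        y_new = float(w @ c / s)
        if y_new == y:
            return y
        y = y_new
    return _switch_scan(c, wl, wu, minimize)  # pragma: no cover - safety net


def type_reduce(
    intervals: np.ndarray,
    consequents: Sequence[float],
    firing_floor: float = 1e-9,
) -> Tuple[float, float, bool]:
    """Karnik-Mendel type reduction over singleton consequents.

    Returns ``(y_l, y_r, fired)`` where [y_l, y_r] brackets every weighted
    average sum(w c)/sum(w) with w_i free in its firing interval.  When even
    the upper firing strengths sum below the floor no admissible average
    exists and the fallback interval [0, 0] is returned with ``fired=False``.
    """
    intervals = np.asarray(intervals, dtype=float)
    c = np.asarray(consequents, dtype=float)
    wl, wu = intervals[:, 0], intervals[:, 1]
    if (wl < 0).any() or (wl > wu).any():
        raise ValueError("firing intervals must satisfy 0 <= lower <= upper")
    if wu.sum() < firing_floor:
        return 0.0, 0.0, False
    order = np.argsort(c, kind="stable")
    c_s, wl_s, wu_s = c[order], wl[order], wu[order]
    y_l = _km_endpoint(c_s, wl_s, wu_s, minimize=True)
    y_r = _km_endpoint(c_s, wl_s, wu_s, minimize=False)
    return y_l, y_r, True


def classify_t2(fv: FVLike, config: Optional[Type2Config] = None) -> Prediction:
    """Interval firing, KM reduction, midpoint defuzzification, 0.5 threshold."""
    if config is None:
        from .config import default_type2_config

        config = default_type2_config()
    intervals = fire_rules_it2(fv, config)
    consequents = np.array([r.consequent for r in config.rules])
    y_l, y_r, fired = type_reduce(intervals, consequents, config.firing_floor)
    likelihood = config.fallback if not fired else (y_l + y_r) / 2.0
    return Prediction(
        likelihood=likelihood,
        label="IBC" if likelihood > config.threshold else "non-IBC",
        rule_strengths={
            "-".join(r.antecedents): (float(lo), float(up))
            for r, (lo, up) in zip(config.rules, intervals)
        },
        fired=fired,
        extras={"reduced_interval": (y_l, y_r)},
    )


class CalibrationError(RuntimeError):
    """No FoU grid point classified the whole calibration set correctly."""


def calibrate_fou(
    cases: Sequence[FeatureVector],
    base_config: Type1Config,
    deltas: Optional[Iterable[float]] = None,
) -> Type2Config:
    """Smallest per-feature FoU widths separating a labeled case set.

    Candidate width triples (one per feature) are taken from ``deltas``
    (default 0.0 to 0.5 in steps of 0.05) and tried in deterministic order —
    ascending total width, then lexicographic — returning the first
    configuration whose Type-2 predictions match every case label.
    """
    if deltas is None:
        deltas = np.round(np.arange(0.0, 0.5001, 0.05), 10)
    deltas = [float(d) for d in deltas]
    if not deltas:
        raise CalibrationError("empty FoU search grid")
    if not cases:
        raise CalibrationError("no labeled cases to calibrate against")
    candidates = sorted(
        itertools.product(deltas, repeat=len(FEATURES)),
        key=lambda t: (round(sum(t), 10), t),
    )
    best_correct, best_triple = -1, None
    for triple in candidates:
        config = make_type2_config(
            base_config, dict(zip(FEATURES, triple))
        )
        correct = sum(
            classify_t2(case, config).label == case.label for case in cases
        )
        if correct == len(cases):
            log.info("FoU calibration: widths %s classify %d/%d correctly",
                     triple, correct, len(cases))
            return config
        if correct > best_correct:
            best_correct, best_triple = correct, triple
    raise CalibrationError(
        f"no FoU widths in the grid classify all {len(cases)} cases; "
        f"best was {best_correct}/{len(cases)} at widths {best_triple}"
    )
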