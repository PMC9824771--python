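"""Type-1 Mamdani fuzzy classifier for the three asymmetry ratios.

Each feature is fuzzified with Low/Medium/High trapezoids; three rules fire
on the diagonal of the linguistic grid:

    (L, L, L) -> IBC      strong left-sided asymmetry (ratios well below 1)
    (M, M, M) -> non-IBC  near-symmetric breasts (ratios near 1)
    (H, H, H) -> IBC      strong right-sided asymmetry (ratios well above 1)

Rule strength is the min t-norm over the antecedent degrees; consequents are
singletons at 1.0 (IBC) and 0.0 (non-IBC), so defuzzification is the
strength-weighted average of singletons.  The crisp output is read as the
likelihood of IBC and thresholded at 0.5 (strict inequality); when no rule
fires the conservative fallback output 0.0 (non-IBC) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .features import FeatureVector
from .membership import TrapezoidMF

__all__ = [
    "FuzzyRule",
    "Type1Config",
    "Prediction",
    "membership_degree",
    "fire_rules",
    "defuzzify",
    "classify_t1",
]

FEATURES = ("f1", "f2", "f3")
LABELS = ("L", "M", "H")


@dataclass(frozen=True)
class FuzzyRule:
    """Antecedent labels for (f1, f2, f3) with a singleton consequent."""

    antecedents: Tuple[str, str, str]
    consequent: float  # 1.0 = IBC, 0.0 = non-IBC

    def __post_init__(self) -> None:
        if len(self.antecedents) != len(FEATURES):
            raise ValueError("a rule needs one antecedent label per feature")
        for lab in self.antecedents:
            if lab not in LABELS:
                raise ValueError(f"unknown linguistic label {lab!r}")
        if self.consequent not in (0.0, 1.0):
            raise ValueError("consequent must be the singleton 0.0 or 1.0")


@dataclass
class Type1Config:
    """Membership functions, rule base and decision parameters."""

    mfs: Dict[str, Dict[str, TrapezoidMF]]
    rules: Tuple[FuzzyRule, ...]
    threshold: float = 0.5
    firing_floor: float = 1e-9  # below this total strength, no rule fired
    fallback: float = 0.0  # output when no rule fires

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.firing_floor <= 0:
            raise ValueError("firing floor must be > 0")
        for feat in FEATURES:
            if feat not in self.mfs:
                raise ValueError(f"missing membership functions for {feat}")


@dataclass
class Prediction:
    """Classifier output for one case."""

    likelihood: float  # crisp IBC likelihood in [0, 1]
    label: str  # "IBC" | "non-IBC"
    rule_strengths: dict = field(default_factory=dict)
    fired: bool = True  # False when the no-rule-fired fallback was used
    extras: dict = field(default_factory=dict)


FVLike = Union[FeatureVector, Sequence[float]]


def _fv_values(fv: FVLike) -> Tuple[float, float, float]:
    vals = fv.values() if isinstance(fv, FeatureVector) else tuple(fv)
    if len(vals) != 3 or not all(np.isfinite(v) for v in vals):
        raise ValueError(f"need three finite feature values, got {vals}")
    return tuple(float(v) for v in vals)


def membership_degree(x: float, mf: TrapezoidMF) -> float:
    """Degree of membership of a feature value in one linguistic term."""
    return float(mf.degree(x))


def fire_rules(fv: FVLike, config: Type1Config) -> np.ndarray:
    """Min t-norm firing strength of every rule, in rule-base order."""
    vals = _fv_values(fv)
    strengths = np.empty(len(config.rules))
    for i, rule in enumerate(config.rules):
        degs = [
            config.mfs[feat][lab].degree(x)
            for feat, lab, x in zip(FEATURES, rule.antecedents, vals)
        ]
        strengths[i] = min(degs)
    return strengths


def defuzzify(
    strengths: np.ndarray, consequents: np.ndarray, config: Type1Config
) -> Tuple[float, bool]:
    """Weighted average of singleton consequents.

    Returns ``(likelihood, fired)``; when the total strength is below the
    firing floor the fallback output is returned with ``fired=False``.
    """
    strengths = np.asarray(strengths, dtype=float)
    consequents = np.asarray(consequents, dtype=float)
    if (strengths < 0).any():
        raise ValueError("rule strengths must be >= 0")
    total = strengths.sum()
    if total < config.firing_floor:
        return config.fallback, False
    return float(strengths @ consequents / total), True


def classify_t1(fv: FVLike, config: Optional[Type1Config] = None) -> Prediction:
    """Fuzzify, fire the rule base, defuzzify, and threshold at 0.5.

    The IBC label requires likelihood strictly greater than the threshold;
    a tie at exactly 0.5 is read as non-IBC.
    """
    if config is None:
        from .config import default_type1_config

        config = default_type1_config()
    strengths = fire_rules(fv, config)
    consequents = np.array([r.consequent for r in config.rules])
    likelihood, fired = defuzzify(strengths, consequents, config)
    return Prediction(
        likelihood=likelihood,
        label="IBC" if likelihood > config.threshold else "non-IBC",
        rule_strengths={
            "-".join(r.antecedents): float(s)
            for r, s in zip(config.rules, strengths)
        },
        fired=fired,
    )
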