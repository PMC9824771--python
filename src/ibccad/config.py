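"""Classifier configuration files: schema, validation, packaged defaults.

Configs are JSON.  Trapezoid breakpoints are 4-element lists; ``null`` in
the first two positions means an open left shoulder (-inf) and in the last
two an open right shoulder (+inf).  The Type-2 schema adds per-feature
``fou_widths``.  The shipped defaults live in ``ibccad/data`` and reproduce
the published confusion counts on the bundled reference cohort; the Type-2
default is the output of :func:`ibccad.fuzzy_type2.calibrate_fou`.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Union

from .fuzzy_type1 import FEATURES, LABELS, FuzzyRule, Type1Config
from .fuzzy_type2 import Type2Config, make_type2_config
from .membership import TrapezoidMF

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "default_type1_config",
    "default_type2_config",
]


class ConfigError(ValueError):
    """A configuration file violated the schema; the message names the field."""


def _breakpoint(value, position: int, where: str) -> float:
    if value is None:
        return -math.inf if position < 2 else math.inf
    if not isinstance(value, (int, float)):
        raise ConfigError(f"{where}: breakpoint {position} must be a number or null")
    return float(value)


def _parse_mf(raw, where: str) -> TrapezoidMF:
    if not isinstance(raw, (list, tuple)) or len(raw) != 4:
        raise ConfigError(f"{where}: expected 4 trapezoid breakpoints")
    pts = [_breakpoint(v, i, where) for i, v in enumerate(raw)]
    try:
        return TrapezoidMF(*pts, label=where.rsplit(".", 1)[-1])
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_type1(doc: dict) -> Type1Config:
    mf_doc = doc.get("membership_functions")
    if not isinstance(mf_doc, dict):
        raise ConfigError("membership_functions: missing or not an object")
    mfs = {}
    for feat in FEATURES:
        if feat not in mf_doc:
            raise ConfigError(f"membership_functions.{feat}: missing")
        mfs[feat] = {}
        for lab in LABELS:
            if lab not in mf_doc[feat]:
                raise ConfigError(f"membership_functions.{feat}.{lab}: missing")
            mfs[feat][lab] = _parse_mf(
                mf_doc[feat][lab], f"membership_functions.{feat}.{lab}"
            )
    rules_doc = doc.get("rules")
    if not isinstance(rules_doc, list) or not rules_doc:
        raise ConfigError("rules: missing or empty")
    rules = []
    for i, r in enumerate(rules_doc):
        try:
            rules.append(FuzzyRule(tuple(r["if"]), float(r["then"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"rules[{i}]: {exc}") from exc
    try:
        return Type1Config(
            mfs=mfs,
            rules=tuple(rules),
            threshold=float(doc.get("threshold", 0.5)),
            firing_floor=float(doc.get("firing_floor", 1e-9)),
            fallback=float(doc.get("fallback", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _load_doc(path_or_doc) -> dict:
    if isinstance(path_or_doc, dict):
        return path_or_doc
    path = Path(path_or_doc)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from exc


def load_config(path_or_doc) -> Union[Type1Config, Type2Config]:
    """Load and validate a classifier config from a JSON file or dict.

    The ``kind`` field selects the schema: ``"type1"`` (default) or
    ``"type2"``.  A Type-2 config is a Type-1 config plus ``fou_widths``.
    """
    doc = _load_doc(path_or_doc)
    kind = doc.get("kind", "type1")
    base = _parse_type1(doc)
    if kind == "type1":
        return base
    if kind != "type2":
        raise ConfigError(f"kind: expected 'type1' or 'type2', got {kind!r}")
    widths_doc = doc.get("fou_widths")
    if not isinstance(widths_doc, dict):
        raise ConfigError("fou_widths: missing or not an object")
    widths = {}
    for feat in FEATURES:
        if feat not in widths_doc:
            raise ConfigError(f"fou_widths.{feat}: missing")
        w = widths_doc[feat]
        if not isinstance(w, (int, float)) or w < 0:
            raise ConfigError(f"fou_widths.{feat}: must be a number >= 0")
        widths[feat] = float(w)
    return make_type2_config(base, widths)


def _mf_to_json(mf: TrapezoidMF) -> list:
    return [None if math.isinf(v) else v for v in (mf.a, mf.b, mf.c, mf.d)]


def save_config(config: Union[Type1Config, Type2Config], path) -> None:
    """Serialize a config back to JSON (round-trips through load_config)."""
    if isinstance(config, Type2Config):
        if config.fou_widths is None:
            raise ConfigError("cannot serialize a Type-2 config without fou_widths")
        base_mfs = {
            feat: {
                lab: TrapezoidMF(
                    *(
                        _restore_base(it2.lower, it2.upper, config.fou_widths[feat])
                    ),
                    label=lab,
                )
                for lab, it2 in terms.items()
            }
            for feat, terms in config.mfs.items()
        }
        doc = {"kind": "type2", "fou_widths": config.fou_widths}
        mfs = base_mfs
    else:
        doc = {"kind": "type1"}
        mfs = config.mfs
    doc.update(
        {
            "threshold": config.threshold,
            "firing_floor": config.firing_floor,
            "fallback": config.fallback,
            "membership_functions": {
                feat: {lab: _mf_to_json(mf) for lab, mf in terms.items()}
                for feat, terms in mfs.items()
            },
            "rules": [
                {"if": list(r.antecedents), "then": r.consequent}
                for r in config.rules
            ],
        }
    )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _restore_base(lower: TrapezoidMF, upper: TrapezoidMF, delta: float) -> tuple:
    """Recover base trapezoid breakpoints from an expanded upper bound."""
    shift = lambda v, s: v + s if math.isfinite(v) else v
    return (
        shift(upper.a, delta),
        shift(upper.b, delta),
        shift(upper.c, -delta),
        shift(upper.d, -delta),
    )


def default_type1_config() -> Type1Config:
    """The shipped Type-1 config (validated against the reference cohort)."""
    with resources.files("ibccad.data").joinpath("type1_config.json").open() as fh:
        return load_config(json.load(fh))


def default_type2_config() -> Type2Config:
    """The shipped Type-2 config (FoU widths from grid calibration)."""
    with resources.files("ibccad.data").joinpath("type2_config.json").open() as fh:
        return load_config(json.load(fh))
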