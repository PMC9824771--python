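"""End-to-end pipeline: image pair in, feature vector and diagnosis out."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .features import FeatureConfig, FeatureVector, compute_features
from .fuzzy_type1 import Prediction, classify_t1
from .fuzzy_type2 import classify_t2
from .image import BilateralStudy, load_image

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Options for one pipeline run."""

    view: Optional[str] = None  # None = auto-detect per side
    model: str = "type1"  # "type1" | "type2"
    classifier_config: Optional[object] = None  # Type1Config | Type2Config
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    case_id: str = ""
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.model not in ("type1", "type2"):
            raise ValueError(f"model must be 'type1' or 'type2', got {self.model!r}")
        if self.view not in (None, "CC", "MLO"):
            raise ValueError(f"view must be 'CC', 'MLO' or None, got {self.view!r}")


@dataclass
class PipelineResult:
    features: FeatureVector
    prediction: Prediction
    stage_log: dict


def run_pipeline(right_img, left_img, run_config: Optional[RunConfig] = None
                 ) -> PipelineResult:
    """Preprocess both sides, extract the asymmetry features, and classify.

    ``right_img``/``left_img`` are file paths (DICOM/PNG/JPEG) or loaded
    :class:`MammogramImage` objects.  When ``out_dir`` is set, a features
    CSV and a prediction JSON (with the per-stage log) are written there.
    """
    cfg = run_config or RunConfig()
    from .image import MammogramImage

    def as_image(obj, side):
        if isinstance(obj, MammogramImage):
            return obj
        return load_image(obj, side=side)

    study = BilateralStudy(
        right=as_image(right_img, "right"),
        left=as_image(left_img, "left"),
        case_id=cfg.case_id,
        view=cfg.view,
    )
    fv = compute_features(study, cfg.feature_config)
    classify = classify_t1 if cfg.model == "type1" else classify_t2
    pred = classify(fv, cfg.classifier_config)
    stage_log = {
        "model": cfg.model,
        "view": cfg.view or "auto",
        "features": {"f1": fv.f1, "f2": fv.f2, "f3": fv.f3},
        "side_stats": {
            side: vars(stats) for side, stats in fv.side_stats.items()
        },
        "rule_strengths": pred.rule_strengths,
        "fired": pred.fired,
    }
    log.info("pipeline: features=(%.3f, %.3f, %.3f) -> %s (likelihood %.3f)",
             fv.f1, fv.f2, fv.f3, pred.label, pred.likelihood)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            [{"case_id": fv.case_id, "f1": fv.f1, "f2": fv.f2, "f3": fv.f3}]
        ).to_csv(out / "features.csv", index=False)
        with open(out / "prediction.json", "w") as fh:
            json.dump(
                {
                    "case_id": fv.case_id,
                    "likelihood": pred.likelihood,
                    "label": pred.label,
                    "stage_log": _jsonable(stage_log),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
    return PipelineResult(features=fv, prediction=pred, stage_log=stage_log)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
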