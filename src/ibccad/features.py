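"""Bilateral asymmetry features: skin-band intensity moments and Otsu density.

IBC presents mammographically as diffuse skin thickening (a bright band along
the breast contour) and increased parenchymal density, usually on one breast
only.  The classifier therefore consumes three right/left ratios measured on
the lower quadrants of each breast:

    f1 = mu_right / mu_left        skin-band mean intensity ratio
    f2 = sigma_right / sigma_left  skin-band intensity SD ratio
    f3 = gamma_right / gamma_left  Otsu-binarized density-fraction ratio

For non-IBC cases all three sit near 1.0; unilateral IBC pushes them below
1.0 (left-sided disease) or above it (right-sided).  Intensity statistics are
computed on the 8-bit quantized histogram: with p(z) the empirical pmf over
z in 0..255, mu = sum z.p(z) and sigma^2 = sum (z-mu)^2 p(z); both are
reported divided by 255 so they live on the same normalized [0, 1] scale as
the bundled reference cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .image import BilateralStudy
from .preprocess import (
    BreastMask,
    NippleLocation,
    detect_orientation,
    locate_nipple,
    remove_artifacts,
    segment_breast,
)

__all__ = [
    "QuadrantROI",
    "SkinBand",
    "IntensityPMF",
    "SideStats",
    "FeatureVector",
    "FeatureConfig",
    "segment_lower_quadrant",
    "extract_skin_band",
    "intensity_pmf",
    "band_moments",
    "otsu_threshold",
    "density_mean",
    "compute_features",
    "load_reference_cohort",
    "cohort_dataframe",
]

log = logging.getLogger(__name__)

SIGMA_FLOOR = 1.0 / 255.0  # quantization resolution; keeps f2 finite


@dataclass
class QuadrantROI:
    """Binary sub-mask of the breast below the nipple line."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("empty lower-quadrant ROI")


@dataclass
class SkinBand:
    """Quadrant pixels within ``width_px`` of the breast arc."""

    mask: np.ndarray
    width_px: int


@dataclass
class IntensityPMF:
    """Empirical probability mass function over 8-bit intensity levels."""

    probs: np.ndarray  # shape (256,)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (256,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must be 256 non-negative probs summing to 1")
        self.probs = p

    def expectation(self, g: Callable[[np.ndarray], np.ndarray]) -> float:
        """E[g(z)] under the pmf."""
        z = np.arange(256, dtype=float)
        return float(np.sum(g(z) * self.probs))


@dataclass
class SideStats:
    """Per-breast statistics on the normalized [0, 1] scale."""

    mu: float
    sigma: float
    gamma: float

    @property
    def variance(self) -> float:
        return self.sigma**2


@dataclass
class FeatureVector:
    """The three right/left asymmetry ratios for one case."""

    f1: float
    f2: float
    f3: float
    case_id: str = ""
    label: Optional[str] = None  # "IBC" | "non-IBC"
    affected_side: Optional[str] = None
    side_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("f1", "f2", "f3"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name}={v} must be finite and > 0")

    def values(self) -> Tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)


@dataclass
class FeatureConfig:
    """Tunables of the feature extractor.

    band_width_fraction : skin-band width as a fraction of the breast's
        minor-axis length (scale invariant); floored at ``band_width_min`` px.
    exclude_band_from_density : drop the skin band from the density ROI so
        the bright band does not inflate the dense-tissue fraction.
    """

    band_width_fraction: float = 0.02
    band_width_min: int = 3
    exclude_band_from_density: bool = True
    density_band_margin_px: int = 2  # extra skin rings kept out of the density ROI


def _quantize(values: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(values, dtype=float) * 255.0).astype(np.int64)


def segment_lower_quadrant(bm: BreastMask, nipple: NippleLocation) -> QuadrantROI:
    """Mask pixels on the inferior side of the nipple line.

    The nipple line splits the breast in half; the inferior half is the side
    with the larger mean row index (rows grow downward).  Pixels exactly on
    the line are assigned to the inferior half.
    """
    rows, cols = np.nonzero(bm.mask)
    nr, nc = nipple.point
    dr, dc = nipple.direction
    s = (rows - nr) * dc - (cols - nc) * dr  # signed side of the line
    if not ((s > 0).any() and (s < 0).any()):
        raise ValueError("nipple line does not intersect the breast mask")
    inferior_positive = rows[s > 0].mean() >= rows[s < 0].mean()
    keep = s >= 0 if inferior_positive else s <= 0
    roi = np.zeros_like(bm.mask)
    roi[rows[keep], cols[keep]] = True
    return QuadrantROI(mask=roi)


def _minor_axis_length(mask: np.ndarray) -> float:
    props = measure.regionprops(mask.astype(np.uint8))
    return float(props[0].axis_minor_length)


def extract_skin_band(
    bm: BreastMask, roi: QuadrantROI, band_width_px: int
) -> SkinBand:
    """Quadrant pixels within ``band_width_px`` of the breast arc.

    Arc pixels within 2 px of the chest-wall junction are dropped first
    (guard margin), and pixels nearer the chest wall than the arc are
    excluded so the band hugs the skin line only.  A width at or beyond the
    breast's minor axis saturates the band to the whole ROI with a warning.
    """
    if band_width_px < 1:
        raise ValueError("band width must be >= 1 px")
    if band_width_px >= _minor_axis_length(bm.mask):
        log.warning("skin band width >= breast minor axis; band = whole ROI")
        return SkinBand(mask=roi.mask.copy(), width_px=band_width_px)

    h, w = bm.mask.shape
    guard = np.abs(bm.arc[:, 1] - bm.chest_col) > 2
    arc = bm.arc[guard]
    if len(arc) == 0:
        raise ValueError("empty breast arc after chest-junction guard")
    arc_mask = np.zeros((h, w), dtype=bool)
    arc_mask[arc[:, 0], arc[:, 1]] = True
    # arc pixels are the outermost skin ring (depth 1), so a band of width w
    # spans depths 1..w, i.e. distance-to-arc 0..w-1
    arc_dist = ndimage.distance_transform_edt(~arc_mask)
    chest_dist = np.abs(np.arange(w)[None, :] - bm.chest_col)
    band = roi.mask & (arc_dist <= band_width_px - 1) & (arc_dist <= chest_dist)
    if not band.any():
        raise ValueError("empty skin band")
    return SkinBand(mask=band, width_px=band_width_px)


def intensity_pmf(values: np.ndarray) -> IntensityPMF:
    """Empirical pmf of the 8-bit quantized intensities of a pixel region."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty pixel region")
    z = _quantize(values)
    counts = np.bincount(z, minlength=256).astype(float)
    return IntensityPMF(probs=counts / counts.sum())


def band_moments(pmf: IntensityPMF) -> Tuple[float, float]:
    """Mean and SD of the quantized intensities, on the [0, 1] scale.

    mu = sum_z z p(z) / 255 and sigma = sqrt(sum_z (z - 255 mu)^2 p(z)) / 255.
    """
    z = np.arange(256, dtype=float)
    mu_z = float(np.sum(z * pmf.probs))
    var_z = float(np.sum((z - mu_z) ** 2 * pmf.probs))
    return mu_z / 255.0, np.sqrt(var_z) / 255.0


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu threshold on the 256-level histogram of a pixel region.

    Returns the level z* in 0..254 maximizing the between-class variance of
    the split {z <= z*} vs {z > z*}; ties break to the lowest threshold.
    """
    z = _quantize(np.asarray(values, dtype=float).ravel())
    if z.size == 0:
        raise ValueError("empty pixel region")
    counts = np.bincount(z, minlength=256).astype(float)
    if np.count_nonzero(counts) < 2:
        raise ValueError("constant region: Otsu threshold undefined")
    p = counts / counts.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)[:-1]  # weight of class {z <= t}, t = 0..254
    m0 = np.cumsum(p * levels)[:-1]
    mu_total = float(np.sum(p * levels))
    valid = (w0 > 0) & (w0 < 1)
    between = np.full(255, -np.inf)
    between[valid] = (mu_total * w0[valid] - m0[valid]) ** 2 / (
        w0[valid] * (1.0 - w0[valid])
    )
    return int(np.argmax(between))  # argmax takes the first (lowest) maximizer


def density_mean(values: np.ndarray, zstar: int) -> float:
    """Mean of the binarized region: fraction of pixels above the threshold."""
    z = _quantize(np.asarray(values, dtype=float).ravel())
    if z.size == 0:
        raise ValueError("empty pixel region")
    return float(np.mean(z > zstar))


def _side_stats(img, view: Optional[str], cfg: FeatureConfig) -> SideStats:
    clean = remove_artifacts(img)
    bm = segment_breast(clean)
    if view is None:
        view, _ = detect_orientation(bm)
    nipple = locate_nipple(bm, view)
    roi = segment_lower_quadrant(bm, nipple)
    width = max(
        cfg.band_width_min,
        int(round(cfg.band_width_fraction * _minor_axis_length(bm.mask))),
    )
    band = extract_skin_band(bm, roi, width)
    mu, sigma = band_moments(intensity_pmf(clean.pixels[band.mask]))
    if cfg.exclude_band_from_density:
        # exclude the skin region with a safety margin so residual bright
        # skin rings cannot inflate the dense-tissue fraction
        exclusion = extract_skin_band(
            bm, roi, width + cfg.density_band_margin_px
        )
        density_mask = roi.mask & ~exclusion.mask
    else:
        density_mask = roi.mask
    if not density_mask.any():
        density_mask = roi.mask
    dvals = clean.pixels[density_mask]
    gamma = density_mean(dvals, otsu_threshold(dvals))
    return SideStats(mu=mu, sigma=sigma, gamma=gamma)


def compute_features(
    study: BilateralStudy, config: Optional[FeatureConfig] = None
) -> FeatureVector:
    """Run the full per-side chain and form the three right/left ratios.

    Statistics are computed on the raw normalized intensities (after artifact
    removal); per-image contrast stretches are deliberately not applied here
    because they would rescale the two sides differently and corrupt the
    ratio semantics.  The sigma ratio floors both SDs at 1/255 (one
    quantization step) so a constant band cannot produce a zero or infinite
    feature.
    """
    cfg = config or FeatureConfig()
    stats = {}
    for side in ("right", "left"):
        try:
            stats[side] = _side_stats(getattr(study, side), study.view, cfg)
        except Exception as exc:
            raise type(exc)(f"{side} breast: {exc}") from exc
    r, l = stats["right"], stats["left"]
    return FeatureVector(
        f1=r.mu / l.mu,
        f2=max(r.sigma, SIGMA_FLOOR) / max(l.sigma, SIGMA_FLOOR),
        f3=r.gamma / l.gamma,
        case_id=study.case_id,
        label=study.label,
        affected_side=study.affected_side,
        side_stats={"right": r, "left": l},
    )


def cohort_dataframe():
    """The bundled 14-case clinical reference cohort as a DataFrame.

    Six biopsy-confirmed IBC cases and eight non-IBC breast cancer cases
    with their published asymmetry features (f1, f2, f3), per-side skin-band
    statistics, and clinical diagnosis.  These printed feature values are
    authoritative for classifier evaluation.
    """
    import pandas as pd

    with resources.files("ibccad.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def load_reference_cohort() -> List[FeatureVector]:
    """The bundled reference cohort as labeled :class:`FeatureVector` s."""
    df = cohort_dataframe()
    out = []
    for row in df.itertuples(index=False):
        out.append(
            FeatureVector(
                f1=float(row.f1),
                f2=float(row.f2),
                f3=float(row.f3),
                case_id=row.case_id,
                label=row.label,
                affected_side=row.affected_side or None,
                side_stats={
                    "mu_right": float(row.mu_right),
                    "mu_left": float(row.mu_left),
                    "sigma_right": float(row.sigma_right),
                    "sigma_left": float(row.sigma_left),
                },
            )
        )
    return out
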