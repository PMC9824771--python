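"""Mammogram preprocessing: artifact removal, breast segmentation,
view/orientation detection, nipple localization, and contrast enhancement.

The processing chain assumes bright-tissue-on-dark-background presentation
(the mammographic norm); inputs with inverted polarity are flipped
automatically.  All coordinates are (row, column), 0-based, origin at the
image's top-left corner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .image import MammogramImage

__all__ = [
    "BreastMask",
    "NippleLocation",
    "BlankImageError",
    "AmbiguousOrientationError",
    "remove_artifacts",
    "segment_breast",
    "detect_orientation",
    "locate_nipple",
    "contrast_stretch",
    "decorrelation_stretch",
]

log = logging.getLogger(__name__)

# MLO is declared when the chest-wall corner triangle (leg = this fraction of
# the image height) has at least this foreground fraction.
PECTORAL_CORNER_FRACTION = 0.25
PECTORAL_CUTOFF = 0.6


class BlankImageError(ValueError):
    """Raised when an image has no detectable foreground."""


class AmbiguousOrientationError(ValueError):
    """Raised when the breast mask touches too many image edges."""


@dataclass
class BreastMask:
    """Segmented breast region with its boundary partition.

    The boundary splits into a chest-wall segment (pixels on the vertical
    image edge the breast abuts) and the curved breast arc (everything else).
    """

    mask: np.ndarray  # bool, single connected component
    chest_side: str  # "left" | "right" (image edge)
    arc: np.ndarray  # (n, 2) int array of (row, col) arc boundary pixels
    chest_wall: np.ndarray  # (m, 2) int array of chest-wall boundary pixels

    @property
    def chest_col(self) -> int:
        return 0 if self.chest_side == "left" else self.mask.shape[1] - 1

    def mirrored(self) -> "BreastMask":
        """The mask of the horizontally flipped image."""
        w = self.mask.shape[1]
        flip = lambda pts: np.column_stack([pts[:, 0], w - 1 - pts[:, 1]])
        return BreastMask(
            mask=np.fliplr(self.mask),
            chest_side="right" if self.chest_side == "left" else "left",
            arc=flip(self.arc),
            chest_wall=flip(self.chest_wall),
        )


@dataclass
class NippleLocation:
    """Nipple coordinates and the halving line through them.

    The nipple line passes through the nipple; its direction is perpendicular
    to the chest wall for CC views and perpendicular to the breast's
    principal axis for MLO views.  It splits the breast into the upper and
    lower halves used for quadrant analysis.
    """

    point: Tuple[int, int]  # (row, col)
    direction: Tuple[float, float]  # unit vector (drow, dcol) along the line


def _foreground_threshold(pixels: np.ndarray) -> float:
    """Background/tissue separation threshold.

    A mammogram histogram typically has three populations — dark background,
    fatty tissue, dense tissue/skin — so a two-class Otsu can land between
    the tissue modes and cut fatty tissue out of the breast.  The lowest
    threshold of a three-class multi-Otsu is used instead; images with too
    few distinct levels fall back to the classic two-class split.
    """
    from skimage import filters

    from .features import otsu_threshold  # local import to avoid a cycle

    try:
        return float(filters.threshold_multiotsu(pixels, classes=3)[0])
    except ValueError:
        return otsu_threshold(pixels.ravel()) / 255.0


def _polarity_corrected(img: MammogramImage) -> MammogramImage:
    """Flip inverted (bright-background) images to bright-foreground."""
    px = img.pixels
    if px.max() - px.min() < 1.0 / 255.0:
        raise BlankImageError("image is constant; no foreground to segment")
    thr = _foreground_threshold(px)
    fg = px > thr
    if not fg.any() or fg.all():
        raise BlankImageError("thresholding produced an empty foreground")
    if px[fg].mean() < px[~fg].mean():  # pragma: no cover - defensive
        raise BlankImageError("degenerate polarity")
    border = np.zeros_like(fg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    if fg[border].mean() > 0.5:
        # foreground dominates the border: white background, invert
        out = img.copy()
        out.pixels = 1.0 - px
        log.info("inverted white-background image")
        return out
    return img


def remove_artifacts(img: MammogramImage) -> MammogramImage:
    """Suppress annotation blocks and tags not attached to the breast.

    Every foreground connected component except the largest is set to
    background (0); the largest component is preserved pixel-for-pixel.
    """
    img = _polarity_corrected(img)
    px = img.pixels
    thr = _foreground_threshold(px)
    fg = px > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise BlankImageError("no foreground components found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    out = img.copy()
    out.pixels = np.where((labels == 0) | (labels == keep), px, 0.0)
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        raise BlankImageError("empty mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def segment_breast(img: MammogramImage) -> BreastMask:
    """Threshold, fill and localize the breast; partition its boundary.

    The chest-wall side is the vertical image edge with more mask pixels.
    A mask touching three or more image edges has no identifiable chest wall
    and raises :class:`AmbiguousOrientationError`.
    """
    img = _polarity_corrected(img)
    px = img.pixels
    thr = _foreground_threshold(px)
    mask = _largest_component(px > thr)
    mask = ndimage.binary_fill_holes(mask)

    h, w = mask.shape
    edge_counts = {
        "top": int(mask[0, :].sum()),
        "bottom": int(mask[-1, :].sum()),
        "left": int(mask[:, 0].sum()),
        "right": int(mask[:, -1].sum()),
    }
    touched = sum(1 for v in edge_counts.values() if v > 0)
    if touched >= 3:
        raise AmbiguousOrientationError(
            f"mask touches {touched} image edges; chest wall is ambiguous"
        )
    chest_side = "left" if edge_counts["left"] >= edge_counts["right"] else "right"
    chest_col = 0 if chest_side == "left" else w - 1

    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    br, bc = np.nonzero(boundary)
    on_chest = np.abs(bc - chest_col) <= 1
    arc = np.column_stack([br[~on_chest], bc[~on_chest]])
    chest_wall = np.column_stack([br[on_chest], bc[on_chest]])
    return BreastMask(mask=mask, chest_side=chest_side, arc=arc, chest_wall=chest_wall)


def detect_orientation(
    bm: BreastMask,
    corner_fraction: float = PECTORAL_CORNER_FRACTION,
    cutoff: float = PECTORAL_CUTOFF,
) -> Tuple[str, float]:
    """Classify the view as CC or MLO from the chest-wall corner occupancy.

    A right triangle with legs ``corner_fraction * height`` is placed in each
    chest-wall corner; if the larger foreground fraction reaches ``cutoff``
    the pectoral muscle is assumed present and the view is MLO (ties go to
    MLO).  Returns ``(view, confidence)`` where confidence is that fraction.
    """
    h, w = bm.mask.shape
    leg = corner_fraction * h
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols if bm.chest_side == "left" else (w - 1 - cols)
    top = (rows / leg + x / leg) <= 1.0
    bottom = ((h - 1 - rows) / leg + x / leg) <= 1.0
    fracs = [bm.mask[tri].mean() for tri in (top, bottom) if tri.any()]
    confidence = float(max(fracs))
    view = "MLO" if confidence >= cutoff else "CC"
    return view, confidence


def _principal_axis(mask: np.ndarray) -> np.ndarray:
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    return evecs[:, np.argmax(evals)]  # (drow, dcol), unit length


def locate_nipple(bm: BreastMask, view: str) -> NippleLocation:
    """Find the nipple as the arc point farthest from the chest wall.

    Ties are broken toward the lowest row index.  The halving line through
    the nipple is perpendicular to the chest wall for CC and perpendicular
    to the breast's principal axis for MLO.
    """
    if len(bm.arc) < 10:
        raise ValueError(f"degenerate breast arc ({len(bm.arc)} points)")
    dist = np.abs(bm.arc[:, 1] - bm.chest_col)
    best = np.lexsort((bm.arc[:, 0], -dist))[0]  # max distance, then min row
    point = (int(bm.arc[best, 0]), int(bm.arc[best, 1]))
    if view == "MLO":
        axis = _principal_axis(bm.mask)
        direction = (-axis[1], axis[0])  # perpendicular to principal axis
    else:
        direction = (0.0, 1.0)  # perpendicular to the vertical chest wall
    norm = float(np.hypot(*direction))
    # orient the direction vector toward increasing column for determinism
    d = np.array(direction) / norm
    if d[1] < 0 or (d[1] == 0 and d[0] < 0):
        d = -d
    return NippleLocation(point=point, direction=(float(d[0]), float(d[1])))


def contrast_stretch(
    img: MammogramImage, low_pct: float = 2.0, high_pct: float = 98.0
) -> MammogramImage:
    """Linear stretch mapping foreground percentiles to [0, 1], clipped.

    Percentiles are taken over nonzero (foreground) pixels so the black
    background does not dominate.  Constant images pass through unchanged.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    px = img.pixels
    # exact zeros are the segmented-out background; ignore them only when
    # they actually form a background (a substantial fraction of the frame)
    fg = px[px > 0] if (px == 0).mean() > 0.05 else px.ravel()
    lo, hi = np.percentile(fg, [low_pct, high_pct])
    if hi <= lo:
        log.warning("contrast_stretch: constant image, no-op")
        return img.copy()
    out = img.copy()
    out.pixels = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    return out


def decorrelation_stretch(
    img: MammogramImage, smooth_sigma: float = 2.0
) -> MammogramImage:
    """Decorrelation stretch adapted to single-channel mammograms.

    A grayscale image has no spectral bands to decorrelate, so a 3-channel
    stack is derived from the intensity image: (intensity, Gaussian-smoothed
    intensity, gradient magnitude).  The channel covariance is whitened, the
    principal-component variances equalized to the mean original channel
    variance, the transform inverted, and the enhanced intensity channel
    rescaled to [0, 1].  This amplifies local intensity differences (band
    versus interior) exactly as a classical multiband decorrelation stretch
    amplifies inter-band differences.  Singular covariance (e.g. constant
    input) falls back to :func:`contrast_stretch`.
    """
    px = img.pixels
    smooth = ndimage.gaussian_filter(px, smooth_sigma)
    grad = np.hypot(ndimage.sobel(px, axis=0), ndimage.sobel(px, axis=1))
    stack = np.stack([px, smooth, grad], axis=-1).reshape(-1, 3)
    mean = stack.mean(axis=0)
    centered = stack - mean
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 1e-12:
        log.warning("decorrelation_stretch: singular covariance, "
                    "falling back to contrast stretch")
        return contrast_stretch(img, 0.0, 100.0)
    target_sd = float(np.sqrt(np.diag(cov).max()))
    transform = evecs @ np.diag(target_sd / np.sqrt(evals)) @ evecs.T
    enhanced = (centered @ transform.T + mean)[:, 0].reshape(px.shape)
    # percentile rescale so gradient-channel outliers cannot compress the
    # bulk contrast, then clip into [0, 1]
    lo, hi = np.percentile(enhanced, [0.5, 99.5])
    out = img.copy()
    if hi > lo:
        out.pixels = np.clip((enhanced - lo) / (hi - lo), 0.0, 1.0)
    else:  # pragma: no cover - near-constant enhanced channel
        out.pixels = np.clip(enhanced, 0.0, 1.0)
    return out
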