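"""Core image containers and file I/O.

Mammograms are held as 2-D float arrays normalized to [0, 1], regardless of
whether they came from DICOM, PNG or JPEG sources.  A :class:`BilateralStudy`
pairs the right and left breast images of one examination — the unit on which
asymmetry features are computed and a diagnosis is made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "MammogramImage",
    "BilateralStudy",
    "load_image",
    "save_png",
]

MIN_SIZE = 64


@dataclass
class MammogramImage:
    """A single-breast mammogram with intensities in [0, 1].

    Parameters
    ----------
    pixels : ndarray
        2-D float array, every value in [0, 1].
    pixel_spacing : tuple of float, optional
        (row, column) spacing in mm, when known (DICOM).
    meta : dict
        Free-form metadata: case id, side hint (``"right"``/``"left"``),
        view hint (``"CC"``/``"MLO"``).
    """

    pixels: np.ndarray
    pixel_spacing: Optional[tuple] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if px.shape[0] < MIN_SIZE or px.shape[1] < MIN_SIZE:
            raise ValueError(
                f"image too small: {px.shape}, need at least {MIN_SIZE}x{MIN_SIZE}"
            )
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite pixels")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def copy(self) -> "MammogramImage":
        return MammogramImage(self.pixels.copy(), self.pixel_spacing, dict(self.meta))


@dataclass
class BilateralStudy:
    """Paired right/left breast images of one case."""

    right: MammogramImage
    left: MammogramImage
    case_id: str = ""
    view: Optional[str] = None  # "CC" | "MLO" | None (auto-detect)
    label: Optional[str] = None  # "IBC" | "non-IBC" | None
    affected_side: Optional[str] = None  # "right" | "left" | None

    def swapped(self) -> "BilateralStudy":
        """Return the study with right and left images exchanged."""
        return BilateralStudy(
            right=self.left,
            left=self.right,
            case_id=self.case_id,
            view=self.view,
            label=self.label,
            affected_side={"right": "left", "left": "right"}.get(
                self.affected_side, self.affected_side
            ),
        )


def _normalize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def load_image(path: str | Path, **meta) -> MammogramImage:
    """Read a mammogram from DICOM, PNG or JPEG into normalized float form.

    DICOM rescale slope/intercept are applied before normalization;
    MONOCHROME1 photometric interpretation is inverted so that dense tissue
    is bright.  Multi-channel images are converted to luma by averaging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    spacing = None
    if suffix in {".dcm", ".dicom"} or suffix == "":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
            arr = arr.max() - arr
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing = (float(ps[0]), float(ps[1]))
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(path)), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=2)
    return MammogramImage(_normalize(arr), pixel_spacing=spacing, meta=dict(meta))


def save_png(img: MammogramImage | np.ndarray, path: str | Path) -> None:
    """Write an image (or bare array in [0,1]) as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    arr = img.pixels if isinstance(img, MammogramImage) else np.asarray(img, float)
    iio.imwrite(str(path), np.clip(np.round(arr * 255), 0, 255).astype(np.uint8))


def save_sidecar(path: str | Path, payload: dict) -> None:
    """Write a small JSON sidecar next to an image artifact."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
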