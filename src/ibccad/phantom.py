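"""Synthetic bilateral mammogram phantoms with known ground truth.

Real inflammatory breast cancer (IBC) mammograms are scarce and not
redistributable, so the imaging pipeline is exercised on simple breast-shaped
phantoms whose skin-band and density parameters are known exactly.  A phantom
breast is a half-ellipse (CC view) or a half-ellipse plus a triangular
pectoral wedge (MLO view) on a black background, with

* a skin band of stated thickness and mean intensity along the curved arc
  (the mammographic correlate of skin thickening, the primary IBC marker),
* a bimodal interior texture realizing a stated dense-tissue fraction
  (the breast-density marker), and
* a nipple bump at the arc apex.

The right-breast image has its chest wall on the image's left edge; the
left-breast image is mirrored, matching standard mammographic presentation.
Everything is driven by an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import BilateralStudy, MammogramImage

__all__ = [
    "SidePhantomParams",
    "PhantomParams",
    "PhantomTruth",
    "generate_bilateral_phantom",
    "make_case_series",
]

PECTORAL_INTENSITY = 0.80


@dataclass
class SidePhantomParams:
    """Geometry and tissue parameters of one phantom breast.

    half_axes_px : (vertical, horizontal) half-axes of the breast ellipse.
    skin_band_thickness_px : thickness of the bright band along the arc.
    skin_band_intensity : mean intensity of the band, in (0, 1].
    skin_band_intensity_sd : SD of the band's intensity texture (gives the
        band a nonzero σ so the σ-asymmetry feature is well defined).
    interior_density_fraction : fraction of interior pixels drawn from the
        dense intensity mode, in [0, 1].
    """

    half_axes_px: Tuple[float, float] = (100.0, 105.0)
    skin_band_thickness_px: int = 4
    skin_band_intensity: float = 0.65
    skin_band_intensity_sd: float = 0.05
    interior_density_fraction: float = 0.35

    def validate(self) -> None:
        a, b = self.half_axes_px
        if a <= 0 or b <= 0:
            raise ValueError("half axes must be positive")
        if self.skin_band_thickness_px < 1:
            raise ValueError("skin band thickness must be >= 1 px")
        if self.skin_band_thickness_px >= min(a, b):
            raise ValueError("skin band thicker than the breast minor half-axis")
        if not (0.0 < self.skin_band_intensity <= 1.0):
            raise ValueError("skin band intensity must lie in (0, 1]")
        if self.skin_band_intensity_sd < 0:
            raise ValueError("skin band intensity SD must be >= 0")
        if not (0.0 <= self.interior_density_fraction <= 1.0):
            raise ValueError("interior density fraction must lie in [0, 1]")


@dataclass
class PhantomParams:
    """Full specification of a bilateral phantom study."""

    view: str = "CC"  # "CC" | "MLO"
    right: SidePhantomParams = field(default_factory=SidePhantomParams)
    left: SidePhantomParams = field(default_factory=SidePhantomParams)
    dense_mode_intensity: float = 0.75
    fatty_mode_intensity: float = 0.30
    noise_sd: float = 0.0
    annotation_artifacts: bool = False
    seed: int = 0
    image_shape: Tuple[int, int] = (256, 256)

    def validate(self) -> None:
        if self.view not in ("CC", "MLO"):
            raise ValueError(f"view must be 'CC' or 'MLO', got {self.view!r}")
        if not (0.0 <= self.fatty_mode_intensity < self.dense_mode_intensity <= 1.0):
            raise ValueError("need 0 <= fatty < dense <= 1 mode intensities")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        for side in (self.right, self.left):
            side.validate()
        h, w = self.image_shape
        for side in (self.right, self.left):
            a, b = side.half_axes_px
            if 2 * a >= h or b >= w - 8:
                raise ValueError("breast ellipse does not fit in the image")


@dataclass
class PhantomTruth:
    """Ground-truth per-side parameters and the derived feature ratios."""

    band_mean: Tuple[float, float]  # (right, left)
    band_sd: Tuple[float, float]
    band_thickness: Tuple[int, int]
    density_fraction: Tuple[float, float]  # realized fraction of dense pixels

    @property
    def f1(self) -> float:
        """True right/left skin-band mean-intensity ratio."""
        return self.band_mean[0] / self.band_mean[1]

    @property
    def f2(self) -> float:
        """True right/left skin-band intensity-SD ratio.

        Floored at one 8-bit quantization step per side, mirroring the
        extractor's convention, so constant bands give a ratio of 1.
        """
        floor = 1.0 / 255.0
        return max(self.band_sd[0], floor) / max(self.band_sd[1], floor)

    @property
    def f3(self) -> float:
        """True right/left dense-fraction ratio."""
        return self.density_fraction[0] / self.density_fraction[1]

    def ratios(self) -> Tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)


def _arc_distance(mask: np.ndarray) -> np.ndarray:
    """Distance of each mask pixel to the curved (non-chest-wall) boundary.

    The chest wall is the left image edge; the mask is padded by edge
    replication on the left/top/bottom so those borders do not count as
    boundary, leaving only the breast arc as "background" for the EDT.
    """
    h, w = mask.shape
    pad = max(h, w)
    padded = np.pad(mask, ((pad, pad), (pad, 0)), mode="edge")
    dist = ndimage.distance_transform_edt(padded)
    return dist[pad : pad + h, pad:]


def _render_side(
    side: SidePhantomParams,
    params: PhantomParams,
    rng: np.random.Generator,
    interior_rng: np.random.Generator,
) -> Tuple[np.ndarray, dict]:
    """Render one breast in right-side orientation (chest wall on the left).

    Returns the image and a dict of realized truth quantities.
    """
    h, w = params.image_shape
    a, b = side.half_axes_px
    cy = h / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    ellipse = (cols / b) ** 2 + ((rows - cy) / a) ** 2 <= 1.0

    mask = ellipse.copy()
    wedge = np.zeros_like(mask)
    if params.view == "MLO":
        wedge_h, wedge_w = 0.45 * h, 0.30 * w
        wedge = (rows / wedge_h + cols / wedge_w) <= 1.0
        mask |= wedge

    # nipple bump: small disk protruding at the arc apex
    nipple_r = 3
    nipple = (rows - cy) ** 2 + (cols - b) ** 2 <= nipple_r**2
    mask |= nipple

    dist = _arc_distance(mask)
    band = mask & (dist <= side.skin_band_thickness_px) & ~wedge
    interior = ellipse & ~band & ~wedge & ~nipple

    img = np.zeros((h, w), dtype=float)
    img[wedge] = PECTORAL_INTENSITY

    # bimodal interior: exactly round(f * N) dense pixels, seeded choice
    idx = np.flatnonzero(interior)
    n_dense = int(round(side.interior_density_fraction * idx.size))
    perm = interior_rng.permutation(idx.size)
    flat = img.ravel()
    flat[idx] = params.fatty_mode_intensity
    flat[idx[perm[:n_dense]]] = params.dense_mode_intensity

    band_tex = side.skin_band_intensity + rng.normal(
        0.0, side.skin_band_intensity_sd, size=int(band.sum())
    )
    img[band] = np.clip(band_tex, 0.0, 1.0)
    img[nipple & ~band] = side.skin_band_intensity

    if params.annotation_artifacts:
        img[8:28, w - 48 : w - 12] = 1.0

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)

    img = np.clip(img, 0.0, 1.0)
    truth = {
        "band_mean": side.skin_band_intensity,
        "band_sd": side.skin_band_intensity_sd,
        "band_thickness": side.skin_band_thickness_px,
        "density_fraction": n_dense / idx.size if idx.size else 0.0,
    }
    return img, truth


def generate_bilateral_phantom(
    params: PhantomParams,
) -> Tuple[BilateralStudy, PhantomTruth]:
    """Generate one bilateral phantom study and its ground truth.

    Deterministic for a fixed ``params.seed``; the two sides use independent
    seeded substreams so that per-side parameters can be varied without
    perturbing the other side's realization.
    """
    params.validate()
    rng_r = np.random.default_rng([params.seed, 0])
    rng_l = np.random.default_rng([params.seed, 1])
    # the dense-pixel placement stream is shared between sides so that
    # equal-parameter sides realize mirrored interior textures (a symmetric
    # phantom really is symmetric); band texture and noise stay independent
    img_r, truth_r = _render_side(
        params.right, params, rng_r, np.random.default_rng([params.seed, 2])
    )
    img_l, truth_l = _render_side(
        params.left, params, rng_l, np.random.default_rng([params.seed, 2])
    )
    img_l = np.fliplr(img_l)  # left breast: chest wall on the right edge

    study = BilateralStudy(
        right=MammogramImage(img_r, meta={"side": "right", "view": params.view}),
        left=MammogramImage(img_l, meta={"side": "left", "view": params.view}),
        view=params.view,
    )
    truth = PhantomTruth(
        band_mean=(truth_r["band_mean"], truth_l["band_mean"]),
        band_sd=(truth_r["band_sd"], truth_l["band_sd"]),
        band_thickness=(truth_r["band_thickness"], truth_l["band_thickness"]),
        density_fraction=(truth_r["density_fraction"], truth_l["density_fraction"]),
    )
    return study, truth


def _ibc_side_params(base: SidePhantomParams) -> SidePhantomParams:
    """Elevate one side's band intensity/thickness and density (IBC pattern)."""
    return replace(
        base,
        # keep intensity + 2 SD below 1.0 so clipping does not distort the band
        skin_band_intensity=min(0.85, base.skin_band_intensity * 1.4),
        skin_band_thickness_px=base.skin_band_thickness_px + 2,
        skin_band_intensity_sd=base.skin_band_intensity_sd * 1.4,
        interior_density_fraction=min(0.85, base.interior_density_fraction + 0.25),
    )


def make_case_series(
    n_ibc: int,
    n_non_ibc: int,
    seed: int,
    view: Optional[str] = None,
    return_truth: bool = False,
):
    """Generate a labeled series of phantom studies.

    IBC-labeled studies have one randomly chosen side with elevated skin-band
    intensity/thickness and dense fraction; non-IBC studies are
    near-symmetric (small seeded right/left jitter).  Views alternate CC/MLO
    unless ``view`` pins one.  With ``return_truth=True`` a parallel list of
    :class:`PhantomTruth` is returned as well.
    """
    if n_ibc < 0 or n_non_ibc < 0:
        raise ValueError("case counts must be >= 0")
    master = np.random.default_rng(seed)
    studies: List[BilateralStudy] = []
    truths: List[PhantomTruth] = []
    labels = ["IBC"] * n_ibc + ["non-IBC"] * n_non_ibc
    for i, label in enumerate(labels):
        case_view = view or ("MLO" if i % 2 else "CC")
        base = SidePhantomParams(
            half_axes_px=(master.uniform(90, 105), master.uniform(95, 112)),
            skin_band_thickness_px=4,
            skin_band_intensity=master.uniform(0.55, 0.68),
            skin_band_intensity_sd=0.05,
            interior_density_fraction=master.uniform(0.30, 0.45),
        )
        jitter = replace(
            base,
            skin_band_intensity=np.clip(
                base.skin_band_intensity * master.uniform(0.97, 1.03), 0.05, 0.95
            ),
            interior_density_fraction=np.clip(
                base.interior_density_fraction * master.uniform(0.95, 1.05), 0.02, 0.9
            ),
        )
        if label == "IBC":
            affected = "right" if master.integers(2) else "left"
            right = _ibc_side_params(base) if affected == "right" else base
            left = _ibc_side_params(jitter) if affected == "left" else jitter
        else:
            affected = None
            right, left = base, jitter
        params = PhantomParams(
            view=case_view,
            right=right,
            left=left,
            noise_sd=0.01,
            seed=int(master.integers(2**31 - 1)),
        )
        study, truth = generate_bilateral_phantom(params)
        study.case_id = f"{label}_{i}"
        study.label = label
        study.affected_side = affected
        studies.append(study)
        truths.append(truth)
    if return_truth:
        return studies, truths
    return studies
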