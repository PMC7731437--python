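"""Threshold classification of normalized quadrat images into GV / SDM / other.

Two per-pixel rules, applied in a fixed order, on normalized bands
(see :mod:`quadratcover.imaging`):

Green vegetation (GV)
    A pixel is GV when its normalized green band exceeds both the red and
    blue bands by more than the thresholds ``g1`` and ``g2``:
    ``(G - R) > g1 and (G - B) > g2``. Green leaves reflect more in the
    green band than in red or blue; dead matter, litter, crust and soil
    do not.

Standing dead matter (SDM)
    Senesced canopy material sits above the understory, receives more
    light, and is therefore brighter than the shaded litter/crust/soil
    below in every visible band. A non-GV pixel is SDM when all three
    bands exceed ``d`` times the image-wide band means:
    ``R > d*mean_R and G > d*mean_G and B > d*mean_B``.

Both rule sets use strict inequalities, so ties are excluded. The band
means are computed over *all* pixels of the normalized image — including
pixels already classified GV — which keeps the SDM brightness reference
stable regardless of how much green cover is present; GV pixels are
excluded only from SDM candidacy. Everything that is neither GV nor SDM
(litter, soil crust, bare soil, rock) falls in the residual "other" class.

Fractional cover is the class pixel count divided by the total pixel count,
expressed in percent; it is therefore invariant to image resolution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .imaging import NormalizedImage

__all__ = [
    "ClassificationParams",
    "BandMeans",
    "ClassMasks",
    "CoverResult",
    "classify_gv",
    "band_means",
    "classify_sdm",
    "compute_cover",
    "classify_image",
    "masks_to_indexed",
    "export_mask_png",
    "COVER_CSV_COLUMNS",
    "cover_csv_row",
    "write_cover_csv",
]

#: Parameter ranges explored in practice; values outside draw a warning in
#: batch runs but are never rejected.
EXPLORED_G_RANGE = (30.0, 70.0)
EXPLORED_D_RANGE = (0.5, 2.0)


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the two classification rules.

    g1, g2:
        Greenness thresholds on the normalized (G - R) and (G - B)
        differences. Default 60 (normalized-DN units); values down to ~30
        are appropriate for high exposure, senesced or bluish foliage.
    d:
        Brightness multiplier on the band means for the SDM rule.
        Default 1; raise it (1–2) when bright litter or soil is being
        mistaken for SDM, lower it (0.5–1) to capture the darker lower
        canopy when standing dead cover is dense.
    """

    g1: float = 60.0
    g2: float = 60.0
    d: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g1) and np.isfinite(self.g2)):
            raise ValueError("g1 and g2 must be finite")
        if not (np.isfinite(self.d) and self.d > 0):
            raise ValueError("d must be a positive finite number")

    def replace(self, **kwargs) -> "ClassificationParams":
        vals = {"g1": self.g1, "g2": self.g2, "d": self.d}
        vals.update({k: v for k, v in kwargs.items() if v is not None})
        return ClassificationParams(**vals)


@dataclass(frozen=True)
class BandMeans:
    """Arithmetic means of the three normalized bands over all pixels."""

    mean_r: float
    mean_g: float
    mean_b: float


@dataclass(frozen=True)
class ClassMasks:
    """Disjoint boolean masks partitioning every pixel."""

    gv: np.ndarray
    sdm: np.ndarray
    other: np.ndarray

    def __post_init__(self) -> None:
        if not (self.gv.shape == self.sdm.shape == self.other.shape):
            raise ValueError("masks must share one shape")
        # pairwise disjoint and jointly exhaustive
        if np.any(self.gv & self.sdm) or np.any(self.gv & self.other) or np.any(
            self.sdm & self.other
        ):
            raise ValueError("masks must be pairwise disjoint")
        if not np.all(self.gv | self.sdm | self.other):
            raise ValueError("masks must cover every pixel")


@dataclass(frozen=True)
class CoverResult:
    """Pixel counts and percent cover for one image."""

    total_pixels: int
    gv_pixels: int
    sdm_pixels: int
    gv_cover: float
    sdm_cover: float


def classify_gv(img: NormalizedImage, g1: float, g2: float) -> np.ndarray:
    """Boolean GV mask: ``(G - R) > g1`` and ``(G - B) > g2`` (strict)."""
    return ((img.green - img.red) > g1) & ((img.green - img.blue) > g2)


def band_means(img: NormalizedImage) -> BandMeans:
    """Means of the normalized bands over all pixels (GV included)."""
    return BandMeans(
        mean_r=float(img.red.mean()),
        mean_g=float(img.green.mean()),
        mean_b=float(img.blue.mean()),
    )


def classify_sdm(
    img: NormalizedImage,
    gv_mask: np.ndarray,
    means: BandMeans,
    d: float,
) -> np.ndarray:
    """Boolean SDM mask among non-GV pixels (strict brightness rule)."""
    if gv_mask.shape != img.shape:
        raise ValueError(
            f"gv_mask shape {gv_mask.shape} does not match image {img.shape}"
        )
    if d <= 0:
        raise ValueError("d must be > 0")
    bright = (
        (img.red > d * means.mean_r)
        & (img.green > d * means.mean_g)
        & (img.blue > d * means.mean_b)
    )
    return ~gv_mask & bright


def compute_cover(masks: ClassMasks) -> CoverResult:
    """Percent cover from class pixel counts."""
    total = masks.gv.size
    if total == 0:
        raise ValueError("cannot compute cover of a zero-pixel image")
    gv = int(masks.gv.sum())
    sdm = int(masks.sdm.sum())
    return CoverResult(
        total_pixels=total,
        gv_pixels=gv,
        sdm_pixels=sdm,
        gv_cover=100.0 * gv / total,
        sdm_cover=100.0 * sdm / total,
    )


def classify_image(
    img: NormalizedImage, params: ClassificationParams = ClassificationParams()
) -> tuple[ClassMasks, CoverResult]:
    """Full per-image pipeline.

    Fixed order: band means first (over all pixels), then the GV rule,
    then the SDM rule restricted to non-GV pixels, then cover fractions.
    """
    means = band_means(img)
    gv = classify_gv(img, params.g1, params.g2)
    sdm = classify_sdm(img, gv, means, params.d)
    masks = ClassMasks(gv=gv, sdm=sdm, other=~(gv | sdm))
    return masks, compute_cover(masks)


#: Palette for exported masks; the *values* 0/1/2 are the contract, the
#: colors are a convenience (other gray, GV green, SDM yellow).
_MASK_PALETTE = {0: (128, 128, 128), 1: (0, 160, 0), 2: (230, 200, 0)}


def masks_to_indexed(masks: ClassMasks) -> np.ndarray:
    """uint8 label image: 0 = other, 1 = GV, 2 = SDM."""
    out = np.zeros(masks.gv.shape, dtype=np.uint8)
    out[masks.gv] = 1
    out[masks.sdm] = 2
    return out


def export_mask_png(masks: ClassMasks, path: str | Path) -> Path:
    """Write the class masks as an 8-bit paletted PNG."""
    path = Path(path)
    im = Image.fromarray(masks_to_indexed(masks), mode="P")
    palette = [0] * 768
    for value, rgb in _MASK_PALETTE.items():
        palette[3 * value : 3 * value + 3] = rgb
    im.putpalette(palette)
    im.save(path)
    return path


COVER_CSV_COLUMNS = [
    "image",
    "total_pixels",
    "gv_pixels",
    "sdm_pixels",
    "gv_cover_pct",
    "sdm_cover_pct",
    "g1",
    "g2",
    "d",
]


def cover_csv_row(
    image: str, result: CoverResult, params: ClassificationParams
) -> dict[str, str]:
    """One covers-CSV row; percentages fixed at 4 decimal places."""
    return {
        "image": image,
        "total_pixels": str(result.total_pixels),
        "gv_pixels": str(result.gv_pixels),
        "sdm_pixels": str(result.sdm_pixels),
        "gv_cover_pct": f"{result.gv_cover:.4f}",
        "sdm_cover_pct": f"{result.sdm_cover:.4f}",
        "g1": f"{params.g1:g}",
        "g2": f"{params.g2:g}",
        "d": f"{params.d:g}",
    }


def write_cover_csv(rows: list[dict[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=COVER_CSV_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return path
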