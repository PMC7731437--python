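"""Reading and radiometric preprocessing of quadrat RGB photographs.

Every classification step in this package operates on *normalized* bands.
Each band of an image is first standardized to zero mean and unit standard
deviation (z-scores over all pixels of that one band of that one image),
then linearly rescaled so its minimum maps to 0 and its maximum to 1023
(a 10-bit range). Standardizing per image and per band removes the additive
and multiplicative part of illumination differences between photographs, so
a single pair of greenness thresholds can be applied across a whole field
campaign.

Normalized values are kept as floating point: the threshold statistics that
guide parameter choice are non-integral, so rounding to integers would
discard information. Rounding (half away from zero) happens only when a
normalized band is exported as a 16-bit grayscale PNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DegenerateBandError, ImageFormatError

#: Upper end of the normalized range (10-bit).
NORMALIZED_MAX = 1023.0

__all__ = [
    "NORMALIZED_MAX",
    "RawImage",
    "CropRect",
    "NormalizedImage",
    "read_image",
    "standardize_band",
    "normalize_band",
    "preprocess_band",
    "preprocess_image",
    "export_normalized_png",
]


@dataclass(frozen=True)
class RawImage:
    """An 8-bit RGB image as delivered by the camera.

    Attributes
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array of digital numbers, band order R, G, B.
    source_path:
        Where the image came from, used in error messages; may be ``None``
        for synthetic images.
    """

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected an H x W x 3 RGB array, got shape {px.shape}"
                + (f" ({self.source_path})" if self.source_path else "")
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("image must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ImageFormatError("digital numbers must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class CropRect:
    """Axis-aligned crop rectangle, 0-based, top-left origin.

    Covers columns ``x0 .. x0+width-1`` and rows ``y0 .. y0+height-1``
    inclusive. Replaces the manual cropping of the photograph to the quadrat
    frame.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("crop width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("crop offsets must be non-negative")

    def check_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(
                f"crop {self} exceeds image bounds {h} x {w}"
            )

    def apply(self, arr: np.ndarray) -> np.ndarray:
        self.check_within(arr.shape[:2])
        return arr[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]


@dataclass(frozen=True)
class NormalizedImage:
    """Per-band standardized-then-rescaled image on the [0, 1023] scale."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("all bands must share one shape")
        if self.red.ndim != 2:
            raise ValueError("bands must be 2-D arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def n_pixels(self) -> int:
        return self.red.size

    def bands(self) -> dict[str, np.ndarray]:
        return {"red": self.red, "green": self.green, "blue": self.blue}


def read_image(path: str | Path) -> RawImage:
    """Read an 8-bit RGB image (JPEG/PNG/TIFF).

    Anything that is not plain 3-band 8-bit RGB — grayscale, palette or
    images with an alpha channel — is rejected with :class:`ImageFormatError`
    rather than silently converted, because band statistics drive the whole
    classification.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode != "RGB":
                detail = "alpha channel present" if "A" in mode else f"mode {mode!r}"
                raise ImageFormatError(
                    f"{path}: expected 8-bit RGB, got {detail}"
                )
            pixels = np.asarray(im, dtype=np.uint8)
    except ImageFormatError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise ImageFormatError(f"{path}: cannot read image ({exc})") from exc
    return RawImage(pixels=pixels, source_path=str(path))


def standardize_band(band: np.ndarray, label: str = "band") -> np.ndarray:
    """Convert one band to z-scores over all of its pixels.

    Uses the population standard deviation (divide by N); the choice is
    irrelevant after min-max rescaling but is fixed here for determinism.

    Raises
    ------
    DegenerateBandError
        If the band is constant (zero standard deviation).
    """
    band = np.asarray(band, dtype=np.float64)
    if band.size == 0:
        raise DegenerateBandError(f"{label}: empty band")
    std = band.std()
    if std == 0.0:
        raise DegenerateBandError(
            f"{label}: constant band (std = 0) cannot be standardized"
        )
    return (band - band.mean()) / std


def normalize_band(std_band: np.ndarray, label: str = "band") -> np.ndarray:
    """Min-max rescale a standardized band onto [0, 1023]."""
    v = np.asarray(std_band, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateBandError(
            f"{label}: constant band (max = min) cannot be normalized"
        )
    # divide first so the extremes map to exactly 0 and 1023
    return NORMALIZED_MAX * ((v - lo) / (hi - lo))


def preprocess_band(band: np.ndarray, label: str = "band") -> np.ndarray:
    """Standardize then normalize one band."""
    return normalize_band(standardize_band(band, label), label)


def preprocess_image(
    raw: RawImage | np.ndarray, crop: CropRect | None = None
) -> NormalizedImage:
    """Crop (optionally) and bring each band onto the normalized scale.

    Band statistics are computed after cropping, so the quadrat frame and
    anything outside it never influence the normalization.
    """
    if isinstance(raw, np.ndarray):
        raw = RawImage(pixels=raw)
    px = raw.pixels
    if crop is not None:
        px = crop.apply(px)
    src = raw.source_path or "<array>"
    out = {}
    for i, name in enumerate(("red", "green", "blue")):
        out[name] = preprocess_band(px[:, :, i], label=f"{src} {name}")
    return NormalizedImage(source_path=raw.source_path, **out)


def export_normalized_png(img: NormalizedImage, prefix: str | Path) -> list[Path]:
    """Write each normalized band as a 16-bit grayscale PNG.

    Values are rounded half away from zero and occupy the low bits
    (0–1023) of the 16-bit range. Returns the written paths, suffixed
    ``_R.png``, ``_G.png``, ``_B.png``.
    """
    prefix = Path(prefix)
    paths = []
    for suffix, band in zip("RGB", (img.red, img.green, img.blue)):
        # round half away from zero; bands are non-negative
        data = np.floor(band + 0.5).astype(np.uint16)
        out = prefix.parent / f"{prefix.name}_{suffix}.png"
        Image.fromarray(data).save(out)
        paths.append(out)
    return paths
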