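"""Raster image container and color-space plumbing.

Images are carried through the smoothing pipeline as floating-point
arrays tagged with a color space.  Three tags exist:

``srgb``
    Gamma-encoded sRGB (or plain grayscale), every channel in [0, 1].
``cielab``
    CIELab under the D65/2° standard observer; L in [0, 100] and the
    opponent axes a, b nominally in [-128, 127].
``unit``
    Channels affinely mapped onto [0, 1] using the *fixed* nominal
    ranges above.  The local-homogeneity operator requires this
    embedding, and using fixed rather than per-image ranges keeps
    homogeneity values comparable across the iteration sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import color as skcolor

logger = logging.getLogger(__name__)

SRGB = "srgb"
CIELAB = "cielab"
UNIT = "unit"

#: Fixed nominal CIELab channel ranges used for the [0, 1] embedding.
LAB_OFFSETS = np.array([0.0, 128.0, 128.0])
LAB_SCALES = np.array([100.0, 255.0, 255.0])


class FormatError(ValueError):
    """Raised for images whose layout the pipeline does not support."""


@dataclass(frozen=True)
class RasterImage:
    """A pixel grid with per-pixel real vectors and a color-space tag.

    ``values`` has shape ``(M, N, k)`` with ``k`` either 1 (grayscale)
    or 3.  All values are finite float64.
    """

    values: np.ndarray
    colorspace: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3 or v.shape[2] not in (1, 3):
            raise FormatError(
                f"expected (M, N, k) with k in {{1, 3}}, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG/TIFF/JPEG file into an sRGB-tagged :class:`RasterImage`.

    Integer samples are rescaled to [0, 1] by the dtype's full range.
    An alpha channel, if present, is dropped (with a log message);
    other channel counts are rejected.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable content
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3 and arr.shape[2] in (2, 4):
        logger.info("dropping alpha channel of %s", path)
        arr = arr[:, :, :-1]
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise FormatError(
            f"{path}: unsupported channel count {arr.shape[2]} (need 1 or 3)"
        )
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return RasterImage(arr, SRGB)


def save_image(img: RasterImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG/TIFF/JPEG, converting to sRGB first."""
    if img.colorspace == CIELAB:
        img = to_srgb(img)
    elif img.colorspace == UNIT:
        raise ValueError("unit-normalized images are evaluation-only; "
                         "convert from the cielab original instead")
    arr = np.clip(img.values, 0.0, 1.0)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def to_cielab(img: RasterImage) -> RasterImage:
    """Convert an sRGB or grayscale image to CIELab (D65/2°).

    Grayscale input is lifted to a luminance-only Lab image
    ``(L, 0, 0)`` with ``L = 100 * gray`` so that one metric and
    reconstruction path serves both k=1 and k=3.
    """
    if img.colorspace == CIELAB:
        logger.warning("to_cielab called on a cielab image; returning as-is")
        return img
    if img.colorspace != SRGB:
        raise ValueError(f"cannot convert colorspace {img.colorspace!r} to cielab")
    if img.channels == 1:
        lab = np.zeros(img.values.shape[:2] + (3,))
        lab[:, :, 0] = 100.0 * np.clip(img.values[:, :, 0], 0.0, 1.0)
        return RasterImage(lab, CIELAB)
    rgb = img.values
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        logger.info("clipping out-of-range sRGB values before Lab conversion")
        rgb = np.clip(rgb, 0.0, 1.0)
    return RasterImage(skcolor.rgb2lab(rgb), CIELAB)


def to_srgb(img: RasterImage) -> RasterImage:
    """Convert CIELab back to sRGB, clipping out-of-gamut colors."""
    if img.colorspace == SRGB:
        return img
    if img.colorspace != CIELAB:
        raise ValueError(f"cannot convert colorspace {img.colorspace!r} to srgb")
    rgb = skcolor.lab2rgb(img.values)
    return RasterImage(np.clip(rgb, 0.0, 1.0), SRGB)


def normalize_unit(img: RasterImage) -> RasterImage:
    """Affinely map channels onto [0, 1] using the fixed nominal ranges.

    CIELab: ``(L/100, (a+128)/255, (b+128)/255)``.  sRGB values are
    already in [0, 1] and only get re-tagged.  Idempotent on unit
    input.  Values outside the nominal range are clipped (and logged).
    """
    if img.colorspace == UNIT:
        return img
    if img.colorspace == SRGB:
        v = img.values
    elif img.colorspace == CIELAB:
        if img.channels != 3:
            raise FormatError("cielab images must have 3 channels")
        v = (img.values + LAB_OFFSETS) / LAB_SCALES
    else:
        raise ValueError(f"cannot normalize colorspace {img.colorspace!r}")
    if v.min() < 0.0 or v.max() > 1.0:
        logger.info("clipping values outside the nominal range during "
                    "unit normalization")
        v = np.clip(v, 0.0, 1.0)
    return RasterImage(v, UNIT)


def write_sequence(images: list[RasterImage], outdir: str | Path,
                   prefix: str = "iter") -> list[Path]:
    """Write an image sequence as zero-padded numbered PNGs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, img in enumerate(images):
        p = outdir / f"{prefix}_{t:04d}.png"
        save_image(img, p)
        paths.append(p)
    return paths
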