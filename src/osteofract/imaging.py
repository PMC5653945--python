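"""Loading and binary preprocessing of grayscale tumor regions of interest.

The processing chain mirrors the standard radiomics preparation of a cropped
MR tumor image: the grayscale ROI is binarized, the tumor area is flood-filled
using a manually drawn mask, the filled frame is inverted (for the
space-filling ratio), and a one-pixel outline of the binarized tumor is
extracted for shape analysis.

Conventions
-----------
* Arrays are stored row-major as ``(height, width)``; coordinates in the
  public API are ``x`` = column, ``y`` = row.
* Rectangles are 0-based and half-open: ``[x0, x1) x [y0, y1)``.
* ``True`` in a :class:`BinaryImage` marks the foreground (tumor-positive)
  phase; the binarization polarity is recorded in the provenance dict.
* Outline extraction uses 8-connectivity and treats pixels beyond the image
  border as background, so frame-touching foreground is part of the outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, InputError, ValidationError

__all__ = [
    "GrayscaleROI",
    "BinaryImage",
    "load_grayscale",
    "save_binary",
    "crop_roi",
    "binarize",
    "extract_outline",
    "flood_fill_roi",
    "invert_filled",
]

#: Planes in which the tumor is imaged.
PLANES = ("coronal", "sagittal", "transversal")

BinaryRole = Literal["binarized", "outline", "filled", "inverted_filled"]

#: Minimum side length accepted when loading an image from disk.  Cropped
#: sub-regions may be smaller (down to 1 px); the floor only guards against
#: accidentally ingesting icons or truncated exports.
MIN_LOAD_SIDE = 8


@dataclass
class GrayscaleROI:
    """A cropped 8-bit grayscale tumor region with an optional tumor mask.

    Parameters
    ----------
    pixels
        ``(height, width)`` uint8 array of intensities in [0, 255].
    mask
        Optional boolean array of the same shape; ``True`` marks pixels
        inside the radiologist-drawn tumor border.
    plane
        Imaging plane, one of ``coronal``, ``sagittal``, ``transversal``.
    image_id
        Free-form identifier used in provenance records and output tables.
    """

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    plane: Optional[str] = None
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D array")
        if self.pixels.size == 0:
            raise ValidationError("pixels must be non-empty")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError("intensities must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValidationError(
                    f"mask shape {self.mask.shape} does not match "
                    f"image shape {self.pixels.shape}"
                )
            if not self.mask.any():
                raise ValidationError("mask must contain at least one pixel")
        if self.plane is not None and self.plane not in PLANES:
            raise ValidationError(f"plane must be one of {PLANES}, got {self.plane!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryImage:
    """A boolean pixel grid tagged by its role in the processing chain."""

    pixels: np.ndarray
    role: BinaryRole
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D boolean array")

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def load_grayscale(
    path: str | Path,
    mask_path: str | Path | None = None,
    *,
    plane: str | None = None,
    image_id: str | None = None,
) -> GrayscaleROI:
    """Read a PNG/TIFF image (8-bit grayscale, or RGB collapsed to luma).

    An optional mask image is binarized at the 8-bit midpoint (values > 127
    are inside the tumor).  Raises :class:`InputError` for unreadable files
    and :class:`ValidationError` when the mask shape does not match.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            gray = np.asarray(im.convert("L"), dtype=np.uint8)
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if min(gray.shape) < MIN_LOAD_SIDE:
        raise ValidationError(
            f"image {path} is {gray.shape[1]}x{gray.shape[0]}; "
            f"sides must be >= {MIN_LOAD_SIDE}"
        )
    mask = None
    if mask_path is not None:
        try:
            with Image.open(mask_path) as im:
                mask_gray = np.asarray(im.convert("L"))
        except (OSError, UnidentifiedImageError, ValueError) as exc:
            raise InputError(f"cannot read mask {mask_path}: {exc}") from exc
        if mask_gray.shape != gray.shape:
            raise ValidationError(
                f"mask shape {mask_gray.shape} does not match image {gray.shape}"
            )
        mask = mask_gray > 127
    return GrayscaleROI(
        pixels=gray,
        mask=mask,
        plane=plane,
        image_id=image_id if image_id is not None else path.stem,
    )


def save_grayscale(img: GrayscaleROI, path: str | Path) -> None:
    """Write the grayscale panel (and its mask, if any) for visual audit."""
    Image.fromarray(img.pixels, mode="L").save(path)


def save_binary(bin_img: BinaryImage, path: str | Path) -> None:
    """Write a binary variant as an 8-bit PNG (foreground = 255)."""
    Image.fromarray(np.where(bin_img.pixels, 255, 0).astype(np.uint8), mode="L").save(path)


def crop_roi(img: GrayscaleROI, rect: tuple[int, int, int, int]) -> GrayscaleROI:
    """Crop a half-open rectangle ``(x0, y0, x1, y1)`` out of the image.

    The mask, when present, is cropped identically; a crop that removes all
    mask pixels drops the mask with a warning.
    """
    x0, y0, x1, y1 = rect
    if not (0 <= x0 < x1 <= img.width and 0 <= y0 < y1 <= img.height):
        raise ValidationError(
            f"rect {rect} is empty or outside the {img.width}x{img.height} frame"
        )
    pixels = img.pixels[y0:y1, x0:x1].copy()
    mask = None
    if img.mask is not None:
        sub = img.mask[y0:y1, x0:x1]
        if sub.any():
            mask = sub.copy()
        else:
            warnings.warn(
                f"crop {rect} of {img.image_id!r} removed all mask pixels; "
                "mask dropped",
                stacklevel=2,
            )
    return GrayscaleROI(pixels=pixels, mask=mask, plane=img.plane, image_id=img.image_id)


def binarize(
    img: GrayscaleROI,
    method: Literal["otsu", "fixed"] = "otsu",
    fixed_threshold: int | None = None,
) -> BinaryImage:
    """Threshold the grayscale ROI; foreground = intensity strictly above it.

    ``otsu`` picks the threshold maximizing between-class variance and is the
    default because the GUI tools conventionally used for this step do the
    same.  A constant image has no Otsu threshold and raises
    :class:`DegenerateInputError` pointing the caller to ``fixed``.
    """
    if method == "otsu":
        if img.pixels.min() == img.pixels.max():
            raise DegenerateInputError(
                "constant image has no Otsu threshold; use method='fixed'"
            )
        threshold = float(threshold_otsu(img.pixels))
    elif method == "fixed":
        if fixed_threshold is None or not 0 <= fixed_threshold <= 255:
            raise ValidationError("fixed_threshold must be given in [0, 255]")
        threshold = float(fixed_threshold)
    else:
        raise ValidationError(f"unknown binarization method {method!r}")
    return BinaryImage(
        pixels=img.pixels > threshold,
        role="binarized",
        provenance={
            "image_id": img.image_id,
            "method": method,
            "threshold": threshold,
            "polarity": "foreground_above_threshold",
        },
    )


_NEIGHBORHOOD_8 = np.ones((3, 3), dtype=bool)


def extract_outline(bin_img: BinaryImage) -> BinaryImage:
    """Keep foreground pixels that touch background in their 8-neighborhood.

    Out-of-frame neighbors count as background, so a region touching the
    border contributes its border pixels to the outline.
    """
    fg = bin_img.pixels
    if not fg.any():
        raise ValidationError("cannot outline an image with empty foreground")
    interior = ndimage.binary_erosion(fg, structure=_NEIGHBORHOOD_8, border_value=0)
    return BinaryImage(
        pixels=fg & ~interior,
        role="outline",
        provenance={**bin_img.provenance, "connectivity": 8},
    )


def flood_fill_roi(bin_img: BinaryImage, mask: np.ndarray) -> BinaryImage:
    """Fill the tumor area: foreground becomes the union of the binarized
    foreground with the mask region.  Pixels outside the mask are unchanged."""
    if mask is None:
        raise ValidationError(
            "flood_fill_roi requires a tumor mask; without one the "
            "space-filling ratio is undefined"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bin_img.pixels.shape:
        raise ValidationError("mask shape does not match binary image")
    if not mask.any():
        raise ValidationError("mask must contain at least one pixel")
    return BinaryImage(
        pixels=bin_img.pixels | mask,
        role="filled",
        provenance=dict(bin_img.provenance),
    )


def invert_filled(filled: BinaryImage) -> BinaryImage:
    """Complement every pixel of the filled frame (tumor becomes background).

    Raises :class:`DegenerateInputError` when the tumor fills the entire
    frame, leaving no foreground after inversion.
    """
    if filled.role not in ("filled", "inverted_filled"):
        raise ValidationError(
            f"invert_filled expects a 'filled' image, got role {filled.role!r}"
        )
    inverted = ~filled.pixels
    if not inverted.any():
        raise DegenerateInputError(
            "tumor fills the whole frame; inverted image has no foreground "
            "and the space-filling ratio is undefined"
        )
    new_role = "inverted_filled" if filled.role == "filled" else "filled"
    return BinaryImage(
        pixels=inverted,
        role=new_role,
        provenance=dict(filled.provenance),
    )
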