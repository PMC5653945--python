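"""Gray level co-occurrence matrices and five Haralick texture features.

A GLCM is the normalized 2-D histogram of gray-level pairs ``(i, j)``
observed at a fixed pixel displacement ``(dx, dy)``; its size is ``G x G``
where ``G`` is the number of gray levels after quantization.  The five
features computed here are

* angular second moment   ASM  = sum P(i,j)^2            (uniformity)
* inverse difference mom. IDM  = sum P(i,j) / (1+(i-j)^2) (local homogeneity)
* contrast                CN   = sum n^2 P_{|i-j|=n}      (tonal frequency)
* correlation             CR   = (sum ij P - mu_x mu_y) / (sigma_x sigma_y)
* entropy                 E    = -sum P log P             (complexity)

where ``mu`` and ``sigma`` are the means and standard deviations of the
marginal distributions ``P_x`` and ``P_y``.  Correlation is undefined on a
constant image (zero marginal SD) and is then reported as NaN.

Defaults follow the common Haralick convention: distance-1 displacements at
0/45/90/135 degrees, symmetric pair counting, features averaged over the
four displacements; entropy in bits.  When the ROI carries a tumor mask,
only pairs with both pixels inside the mask contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .imaging import GrayscaleROI

__all__ = [
    "GLCM",
    "GLCMFeatures",
    "GLCMConfig",
    "quantize",
    "compute_glcm",
    "feature_asm",
    "feature_idm",
    "feature_contrast",
    "feature_correlation",
    "feature_entropy",
    "glcm_features",
]

#: Distance-1 displacements at 0, 45, 90 and 135 degrees in (dx, dy) with
#: y increasing downwards.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((1, 0), (1, -1), (0, 1), (-1, 1))


@dataclass
class GLCM:
    """A normalized co-occurrence matrix with its marginal statistics."""

    p: np.ndarray
    g: int
    offset: tuple[int, int]
    symmetric: bool
    mu_x: float = field(init=False)
    mu_y: float = field(init=False)
    sigma_x: float = field(init=False)
    sigma_y: float = field(init=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.g, self.g):
            raise ValidationError(f"matrix must be {self.g}x{self.g}")
        if (self.p < 0).any():
            raise ValidationError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValidationError("probabilities must sum to 1")
        levels = np.arange(self.g, dtype=float)
        px = self.p.sum(axis=1)
        py = self.p.sum(axis=0)
        self.mu_x = float(levels @ px)
        self.mu_y = float(levels @ py)
        self.sigma_x = float(math.sqrt(max(((levels - self.mu_x) ** 2) @ px, 0.0)))
        self.sigma_y = float(math.sqrt(max(((levels - self.mu_y) ** 2) @ py, 0.0)))


@dataclass
class GLCMFeatures:
    """The five texture features; correlation is NaN when undefined."""

    s_asm: float
    s_idm: float
    s_cn: float
    s_cr: float
    s_e: float


@dataclass
class GLCMConfig:
    levels: int = 256
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS
    symmetric: bool = True
    log_base: float = 2.0
    use_mask: bool = True


def quantize(
    img: GrayscaleROI | np.ndarray, levels: int
) -> np.ndarray:
    """Uniformly bin 8-bit intensities into ``levels`` equal-width bins.

    Returns an integer image with values in ``0 .. levels-1`` via
    ``floor(v * levels / 256)``.
    """
    if not 2 <= levels <= 256:
        raise ValidationError("levels must lie in [2, 256]")
    pixels = img.pixels if isinstance(img, GrayscaleROI) else np.asarray(img)
    if pixels.min() < 0 or pixels.max() > 255:
        raise ValidationError("intensities must lie in [0, 255]")
    return (pixels.astype(np.int64) * levels) // 256


def compute_glcm(
    indexed: np.ndarray,
    offset: tuple[int, int],
    symmetric: bool = True,
    mask: Optional[np.ndarray] = None,
    levels: Optional[int] = None,
) -> GLCM:
    """Count ordered gray-level pairs at displacement ``(dx, dy)``.

    A pair joins the pixel at ``(x, y)`` with the one at ``(x+dx, y+dy)``;
    pairs leaving the frame (or, with a mask, pairs whose members are not
    both inside it) are discarded.  Symmetric mode also counts every
    reverse pair.  Counts are normalized to probabilities.
    """
    indexed = np.asarray(indexed)
    if indexed.ndim != 2:
        raise ValidationError("indexed image must be 2-D")
    dx, dy = offset
    if (dx, dy) == (0, 0):
        raise ValidationError("offset must be nonzero")
    g = int(levels) if levels is not None else int(indexed.max()) + 1
    if indexed.min() < 0 or indexed.max() >= g:
        raise ValidationError(f"indexed values must lie in [0, {g - 1}]")
    h, w = indexed.shape
    # source window such that (x+dx, y+dy) stays inside the frame
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    yd = slice(max(0, dy), min(h, h + dy))
    xd = slice(max(0, dx), min(w, w + dx))
    i = indexed[ys, xs].ravel()
    j = indexed[yd, xd].ravel()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != indexed.shape:
            raise ValidationError("mask shape does not match image")
        keep = (mask[ys, xs] & mask[yd, xd]).ravel()
        i, j = i[keep], j[keep]
    if i.size == 0:
        raise ValidationError(
            f"no valid pixel pairs for offset {offset} on a {h}x{w} frame"
        )
    counts = np.bincount(i * g + j, minlength=g * g).reshape(g, g).astype(float)
    if symmetric:
        counts = counts + counts.T
    return GLCM(p=counts / counts.sum(), g=g, offset=(dx, dy), symmetric=symmetric)


def feature_asm(m: GLCM) -> float:
    """Angular second moment: sum of squared probabilities."""
    return float((m.p**2).sum())


def feature_idm(m: GLCM) -> float:
    """Inverse difference moment: sum P/(1 + (i-j)^2)."""
    i, j = np.indices(m.p.shape)
    return float((m.p / (1.0 + (i - j) ** 2)).sum())


def feature_contrast(m: GLCM) -> float:
    """Contrast: sum over n of n^2 times the total mass at |i-j| = n."""
    i, j = np.indices(m.p.shape)
    n = np.abs(i - j)
    return float((m.p * n.astype(float) ** 2).sum())


def feature_correlation(m: GLCM) -> float:
    """Gray-tone linear dependence; NaN when a marginal SD is zero."""
    if m.sigma_x == 0.0 or m.sigma_y == 0.0:
        return math.nan
    i, j = np.indices(m.p.shape)
    return float(((i * j * m.p).sum() - m.mu_x * m.mu_y) / (m.sigma_x * m.sigma_y))


def feature_entropy(m: GLCM, base: float = 2.0) -> float:
    """Shannon entropy of the pair distribution; 0 log 0 := 0."""
    p = m.p[m.p > 0]
    return float(-(p * (np.log(p) / math.log(base))).sum())


def glcm_features(
    gray: GrayscaleROI, cfg: GLCMConfig | None = None
) -> GLCMFeatures:
    """Quantize, build one GLCM per configured offset, average each feature.

    Correlation is averaged over the offsets where it is defined; it is NaN
    only if undefined at every offset (constant image).
    """
    cfg = cfg or GLCMConfig()
    indexed = quantize(gray, cfg.levels)
    mask = gray.mask if cfg.use_mask else None
    asm_v, idm_v, cn_v, cr_v, e_v = [], [], [], [], []
    for offset in cfg.offsets:
        m = compute_glcm(indexed, offset, cfg.symmetric, mask, levels=cfg.levels)
        asm_v.append(feature_asm(m))
        idm_v.append(feature_idm(m))
        cn_v.append(feature_contrast(m))
        cr_v.append(feature_correlation(m))
        e_v.append(feature_entropy(m, cfg.log_base))
    cr = np.asarray(cr_v, dtype=float)
    cr_mean = float(np.nanmean(cr)) if np.isfinite(cr).any() else math.nan
    return GLCMFeatures(
        s_asm=float(np.mean(asm_v)),
        s_idm=float(np.mean(idm_v)),
        s_cn=float(np.mean(cn_v)),
        s_cr=cr_mean,
        s_e=float(np.mean(e_v)),
    )
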