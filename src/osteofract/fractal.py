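"""Box-counting fractal dimension, gliding-box lacunarity, and the
space-filling ratio (SFR).

The box dimension of a planar binary pattern is estimated by covering the
frame with a square grid of cell side ``r`` and counting the cells ``N(r)``
that contain at least one foreground pixel.  For a (statistically)
self-similar pattern the counts follow a power law

    N(r) = const * r**(-D),

and ``D`` is recovered as the magnitude of the slope of an ordinary
least-squares fit of ``log N`` on ``log r``.  Two variants are used on
tumor images: ``D_bin`` on the binarized image (pixel-distribution
complexity) and ``D_out`` on its extracted outline (border shape
complexity).

The space-filling ratio normalizes the dimension against tumor-vs-frame
size variation: it is the box dimension of the tumor-flood-filled frame
divided by the box dimension of the whole-frame complement of that image.
Because numerator and denominator suffer the same finite-size effects, the
ratio is comparable across ROIs of very different tumor/background
proportions.

Lacunarity is the gliding-box heterogeneity measure of Allain & Cloitre:
an ``r x r`` window slides over every position (stride 1), the window mass
``M`` (foreground count) is recorded, and

    Lambda(r) = var(M) / mean(M)**2 + 1,

so homogeneous patterns sit at 1 and gappier, more clustered patterns score
higher.  The summary statistic is the arithmetic mean of ``Lambda(r)`` over
the box-size schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .imaging import (
    BinaryImage,
    GrayscaleROI,
    binarize,
    extract_outline,
    flood_fill_roi,
    invert_filled,
)

__all__ = [
    "BoxCountCurve",
    "LacunarityResult",
    "FractalFeatures",
    "FractalConfig",
    "default_box_sizes",
    "box_count",
    "fit_dimension",
    "lacunarity",
    "compute_dbin",
    "compute_dout",
    "compute_sfr",
    "fractal_features",
]


@dataclass
class BoxCountCurve:
    """Box sizes, occupancy counts, and (after fitting) the dimension."""

    sizes: np.ndarray
    counts: np.ndarray
    dimension: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.sizes.shape != self.counts.shape:
            raise ValidationError("sizes and counts must have equal length")


@dataclass
class LacunarityResult:
    """Per-size gliding-box lacunarity and its mean over sizes."""

    sizes: np.ndarray
    lambda_per_size: np.ndarray
    lambda_summary: float


@dataclass
class FractalFeatures:
    """The four morphometric features of one grayscale ROI.

    ``sfr`` is NaN when no tumor mask is available or the inversion is
    degenerate; the reason is recorded in ``notes``.
    """

    d_bin: float
    d_out: float
    sfr: float
    lacunarity: float
    notes: dict = field(default_factory=dict)


@dataclass
class FractalConfig:
    """Knobs of the fractal feature chain.

    box_sizes
        Explicit box-side schedule; ``None`` selects powers of two from 2 up
        to ``min(height, width) // 2``.
    binarize_method / fixed_threshold
        Passed through to :func:`osteofract.imaging.binarize`.
    min_sizes
        The default schedule refuses to produce fewer sizes than this; the
        fit itself always needs at least 3 points (a 2-point log-log fit is
        perfect and meaningless).
    """

    box_sizes: Optional[Sequence[int]] = None
    binarize_method: str = "otsu"
    fixed_threshold: Optional[int] = None
    min_sizes: int = 4


def default_box_sizes(shape: tuple[int, int], min_sizes: int = 4) -> np.ndarray:
    """Powers of two from 2 up to half the shorter side."""
    limit = min(shape) // 2
    sizes = []
    r = 2
    while r <= limit:
        sizes.append(r)
        r *= 2
    if len(sizes) < min_sizes:
        raise ValidationError(
            f"frame {shape} supports only {len(sizes)} box sizes; "
            f"need at least {min_sizes}"
        )
    return np.asarray(sizes, dtype=int)


def box_count(bin_img: BinaryImage, sizes: Sequence[int]) -> BoxCountCurve:
    """Count occupied grid cells for each box side in ``sizes``.

    The grid is anchored at the top-left corner; partial cells along the
    right/bottom edges are counted like full cells.
    """
    fg = bin_img.pixels
    if not fg.any():
        raise ValidationError("box_count needs at least one foreground pixel")
    h, w = fg.shape
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0 or (sizes < 1).any() or (sizes > min(h, w)).any():
        raise ValidationError(
            f"box sizes must lie in [1, {min(h, w)}] for a {h}x{w} frame"
        )
    counts = np.empty(sizes.size, dtype=int)
    for k, r in enumerate(sizes):
        ph, pw = (-h) % r, (-w) % r
        padded = np.pad(fg, ((0, ph), (0, pw)), constant_values=False)
        blocks = padded.reshape(padded.shape[0] // r, r, padded.shape[1] // r, r)
        counts[k] = int(blocks.any(axis=(1, 3)).sum())
    return BoxCountCurve(sizes=sizes, counts=counts)


def fit_dimension(curve: BoxCountCurve, min_sizes: int = 3) -> BoxCountCurve:
    """OLS fit of log N on log r; dimension is the slope magnitude.

    Natural logarithms are used; the slope is base-invariant.
    """
    if curve.sizes.size < min_sizes:
        raise ValidationError(f"need at least {min_sizes} (r, N) pairs to fit")
    if (curve.counts <= 0).any() or (curve.sizes <= 0).any():
        raise ValidationError("sizes and counts must be positive for a log-log fit")
    log_r = np.log(curve.sizes)
    log_n = np.log(curve.counts)
    if np.ptp(log_r) == 0:
        raise ValidationError("box sizes have zero variance; cannot fit a slope")
    slope, intercept = np.polyfit(log_r, log_n, 1)
    fitted = slope * log_r + intercept
    ss_res = float(np.sum((log_n - fitted) ** 2))
    ss_tot = float(np.sum((log_n - log_n.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return BoxCountCurve(
        sizes=curve.sizes,
        counts=curve.counts,
        dimension=abs(float(slope)),
        intercept=float(intercept),
        r_squared=r2,
    )


def _dimension_of(bin_img: BinaryImage, cfg: FractalConfig) -> float:
    sizes = (
        np.asarray(cfg.box_sizes, dtype=int)
        if cfg.box_sizes is not None
        else default_box_sizes(bin_img.pixels.shape, cfg.min_sizes)
    )
    return fit_dimension(box_count(bin_img, sizes)).dimension


def compute_dbin(gray: GrayscaleROI, cfg: FractalConfig | None = None) -> float:
    """Box dimension of the binarized image (pixel-distribution complexity)."""
    cfg = cfg or FractalConfig()
    binary = binarize(gray, cfg.binarize_method, cfg.fixed_threshold)
    return _dimension_of(binary, cfg)


def compute_dout(gray: GrayscaleROI, cfg: FractalConfig | None = None) -> float:
    """Box dimension of the binarized image's outline (border complexity)."""
    cfg = cfg or FractalConfig()
    binary = binarize(gray, cfg.binarize_method, cfg.fixed_threshold)
    return _dimension_of(extract_outline(binary), cfg)


def lacunarity(bin_img: BinaryImage, sizes: Sequence[int]) -> LacunarityResult:
    """Gliding-box lacunarity, stride 1, Lambda(r) = var/mean**2 + 1.

    Window masses are computed with an integral image, so the cost is linear
    in the frame size per box size.
    """
    fg = bin_img.pixels
    if not fg.any():
        raise ValidationError("lacunarity needs at least one foreground pixel")
    h, w = fg.shape
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0 or (sizes < 1).any() or (sizes >= min(h, w)).any():
        raise ValidationError(
            f"gliding-box sizes must lie in [1, {min(h, w) - 1}] for a {h}x{w} frame"
        )
    # integral image with a zero border row/column
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(fg, axis=0), axis=1, out=sat[1:, 1:])
    lambdas = np.empty(sizes.size, dtype=float)
    for k, r in enumerate(sizes):
        masses = (
            sat[r:, r:] - sat[:-r, r:] - sat[r:, :-r] + sat[:-r, :-r]
        ).astype(float)
        mean = masses.mean()
        lambdas[k] = masses.var() / mean**2 + 1.0
    return LacunarityResult(
        sizes=sizes, lambda_per_size=lambdas, lambda_summary=float(lambdas.mean())
    )


def compute_sfr(
    gray: GrayscaleROI,
    mask: np.ndarray | None = None,
    cfg: FractalConfig | None = None,
    *,
    swap: bool = False,
) -> float:
    """Space-filling ratio: D(tumor-filled frame) / D(inverted filled frame).

    ``mask`` defaults to the ROI's own tumor mask.  ``swap=True`` exchanges
    numerator and denominator, which is occasionally useful for symmetry
    checks; the reported feature always uses the default orientation.
    """
    cfg = cfg or FractalConfig()
    if mask is None:
        mask = gray.mask
    if mask is None:
        raise ValidationError("compute_sfr requires a tumor mask")
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise DegenerateInputError(
            "mask covers the whole frame; the inverted image is empty and "
            "SFR is undefined"
        )
    binary = binarize(gray, cfg.binarize_method, cfg.fixed_threshold)
    filled = flood_fill_roi(binary, mask)
    inverted = invert_filled(filled)
    d_filled = _dimension_of(filled, cfg)
    d_inverted = _dimension_of(inverted, cfg)
    if swap:
        return d_inverted / d_filled
    return d_filled / d_inverted


def fractal_features(
    gray: GrayscaleROI, cfg: FractalConfig | None = None
) -> FractalFeatures:
    """All four morphometric features of one ROI.

    SFR is recorded as NaN (with the reason in ``notes``) when the ROI has
    no mask or the mask covers the whole frame.
    """
    cfg = cfg or FractalConfig()
    binary = binarize(gray, cfg.binarize_method, cfg.fixed_threshold)
    sizes = (
        np.asarray(cfg.box_sizes, dtype=int)
        if cfg.box_sizes is not None
        else default_box_sizes(binary.pixels.shape, cfg.min_sizes)
    )
    d_bin = fit_dimension(box_count(binary, sizes)).dimension
    d_out = fit_dimension(box_count(extract_outline(binary), sizes)).dimension
    lac_sizes = sizes[sizes < min(binary.pixels.shape)]
    lam = lacunarity(binary, lac_sizes).lambda_summary
    notes = {
        "threshold": binary.provenance.get("threshold"),
        "n_sizes": int(sizes.size),
    }
    if gray.mask is None:
        sfr = math.nan
        notes["sfr"] = "missing: no tumor mask"
    else:
        try:
            sfr = compute_sfr(gray, gray.mask, cfg)
        except DegenerateInputError as exc:
            sfr = math.nan
            notes["sfr"] = f"missing: {exc}"
    return FractalFeatures(
        d_bin=d_bin, d_out=d_out, sfr=sfr, lacunarity=lam, notes=notes
    )
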