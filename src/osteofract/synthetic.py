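"""Synthetic inputs: known-dimension fractals, tumor phantoms, and cohorts.

Three tiers of synthetic data feed the pipeline and its tests:

1. **Known-dimension binary fixtures** (filled square, line, Sierpinski
   carpet/triangle, random dust) whose analytic box dimensions validate the
   fractal estimators.
2. **Grayscale tumor phantoms**: a fractional-Brownian-style noise field
   whose spectral exponent is set by a roughness parameter ``H`` (smaller
   ``H`` = rougher texture = higher box dimension), overlaid with a
   star-convex irregular tumor mask and an intensity offset inside the
   tumor.  This emulates the cropped MR ROI + radiologist-drawn border that
   the real pipeline consumes.
3. **Two-group cohorts** with the response-effect structure reported for
   osteosarcoma induction chemotherapy: space-filling ratio (SFR)
   distributed 0.94 +/- 0.01 in poor responders vs 0.91 +/- 0.02 in good
   responders, 12 good / 10 poor patients, 3 planes x 2 images per patient.
   The *feature tier* draws per-image feature values from those group
   distributions directly (for the statistics layer); the *image tier*
   calibrates phantom mask sizes so the measured SFR approximates the same
   targets and writes actual PNG images, masks, and a cohort CSV.

Every generator is a pure function of its configuration, seed included.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fractal import FractalConfig, compute_sfr
from .imaging import PLANES, BinaryImage, GrayscaleROI, save_grayscale
from PIL import Image

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "make_known_fractal",
    "make_tumor_phantom",
    "make_cohort",
    "make_feature_cohort",
    "make_image_cohort",
]

#: Feature columns emitted for every image, in canonical order.
FEATURE_COLUMNS = (
    "d_bin",
    "d_out",
    "sfr",
    "lambda",
    "s_asm",
    "s_idm",
    "s_cn",
    "s_cr",
    "s_e",
)

ANALYTIC_DIMENSIONS = {
    "filled_square": 2.0,
    "line": 1.0,
    "sierpinski_carpet": math.log(8) / math.log(3),
    "sierpinski_triangle": math.log(3) / math.log(2),
    "koch_quadric": 1.5,
}


def make_known_fractal(
    kind: str,
    level: int | None = None,
    size: int | None = None,
    density: float = 0.01,
    seed: int = 0,
) -> BinaryImage:
    """Deterministic binary patterns with known box dimension.

    ``level`` drives the self-similar constructions (carpet: 3**level grid;
    triangle: 2**level grid; quadric Koch island: unit square side
    4**level); ``size`` drives the non-recursive ones.  The analytic
    dimension is attached as provenance metadata.
    """
    if kind == "filled_square":
        if size is None or size < 1:
            raise ValidationError("filled_square requires size >= 1")
        pixels = np.ones((size, size), dtype=bool)
    elif kind == "line":
        if size is None or size < 1:
            raise ValidationError("line requires size >= 1")
        pixels = np.zeros((size, size), dtype=bool)
        pixels[size // 2, :] = True
    elif kind == "sierpinski_carpet":
        if level is None or not 1 <= level <= 7:
            raise ValidationError("carpet level must be in [1, 7]")
        n = 3**level
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pixels = np.ones((n, n), dtype=bool)
        for _ in range(level):
            pixels &= ~((i % 3 == 1) & (j % 3 == 1))
            i, j = i // 3, j // 3
    elif kind == "sierpinski_triangle":
        if level is None or not 1 <= level <= 11:
            raise ValidationError("triangle level must be in [1, 11]")
        n = 2**level
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pixels = (i & j) == 0
    elif kind == "koch_quadric":
        if level is None or not 1 <= level <= 4:
            raise ValidationError("koch_quadric level must be in [1, 4]")
        pixels = _koch_quadric_island(level)
    elif kind == "random_dust":
        if size is None or size < 2:
            raise ValidationError("random_dust requires size >= 2")
        rng = np.random.default_rng(seed)
        pixels = rng.random((size, size)) < density
        if not pixels.any():  # guarantee the nonempty-foreground invariant
            pixels[size // 2, size // 2] = True
    else:
        raise ValidationError(f"unknown fractal kind {kind!r}")
    return BinaryImage(
        pixels=pixels,
        role="binarized",
        provenance={
            "kind": kind,
            "analytic_dimension": ANALYTIC_DIMENSIONS.get(kind),
            "level": level,
            "size": size,
            "seed": seed,
        },
    )


def _koch_quadric_island(level: int) -> np.ndarray:
    """Rasterize the boundary of a quadric Koch island (8-segment, scale-1/4
    generator; boundary dimension log 8 / log 4 = 1.5) as a pixel curve.

    The island starts as a square of side 4**level so every vertex stays on
    the integer lattice.
    """
    side = 4**level
    # unit-step generator applied to each axis-aligned segment:
    # F -> F L F R F R F F L F L F R F   (turtle moves, L/R = 90-degree turns)
    pattern = "FLFRFRFFLFLFRF"

    def expand(moves: str) -> str:
        out = []
        for m in moves:
            out.append(pattern if m == "F" else m)
        return "".join(out)

    moves = "F" + "RF" * 3  # the four sides of the initial square
    for _ in range(level):
        moves = expand(moves)
    # walk the turtle; headings: 0=+x, 1=+y, 2=-x, 3=-y
    step = 1
    x = y = 0
    heading = 0
    pts = [(0, 0)]
    for m in moves:
        if m == "F":
            dx, dy = [(1, 0), (0, 1), (-1, 0), (0, -1)][heading]
            x, y = x + dx * step, y + dy * step
            pts.append((x, y))
        elif m == "R":
            heading = (heading + 1) % 4
        elif m == "L":
            heading = (heading - 1) % 4
    pts_arr = np.asarray(pts)
    xs, ys = pts_arr[:, 0], pts_arr[:, 1]
    # shift by a multiple of the largest natural box size (4**level) so a
    # top-left-anchored grid stays aligned with the construction lattice at
    # every scale r = 4**k, keeping the box counts exactly self-similar
    sx = -(xs.min() // side) * side
    sy = -(ys.min() // side) * side
    xs = xs + sx
    ys = ys + sy
    grid = np.zeros((ys.max() + 2, xs.max() + 2), dtype=bool)
    grid[ys, xs] = True
    return grid


@dataclass
class PhantomConfig:
    """Configuration of one grayscale tumor phantom."""

    frame: int = 128
    roughness: float = 0.5  # H in (0, 1); smaller = rougher field
    mask_area_fraction: float = 0.25
    mask_harmonics: int = 5
    mask_amplitude: float = 0.25
    contrast: float = 60.0  # intensity offset added inside the tumor
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.roughness < 1.0:
            raise ValidationError("roughness H must lie in (0, 1)")
        if not 0.0 < self.mask_area_fraction < 1.0:
            raise ValidationError("mask area fraction must lie strictly in (0, 1)")
        if self.frame < 32:
            raise ValidationError("frame must be at least 32 px")


def _spectral_field(frame: int, h_exp: float, rng: np.random.Generator) -> np.ndarray:
    """fBm-style surface via spectral synthesis: amplitude ~ f**-(H+1)."""
    fy = np.fft.fftfreq(frame)[:, None]
    fx = np.fft.fftfreq(frame)[None, :]
    f = np.hypot(fx, fy)
    f[0, 0] = np.inf  # kill the DC term
    amplitude = f ** (-(h_exp + 1.0))
    phase = rng.uniform(0, 2 * np.pi, (frame, frame))
    spectrum = amplitude * np.exp(1j * phase)
    field = np.fft.ifft2(spectrum).real
    field -= field.min()
    peak = field.max()
    return field / peak if peak > 0 else field


def _star_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Star-convex mask from a random radial harmonic profile, scaled so the
    enclosed area matches the configured fraction of the frame."""
    frame = cfg.frame
    theta_coeff = rng.uniform(-1, 1, cfg.mask_harmonics)
    theta_phase = rng.uniform(0, 2 * np.pi, cfg.mask_harmonics)
    yy, xx = np.indices((frame, frame))
    cy = cx = (frame - 1) / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    rho = np.ones_like(theta)
    for k in range(cfg.mask_harmonics):
        rho += (
            cfg.mask_amplitude
            * theta_coeff[k]
            / (k + 1)
            * np.cos((k + 1) * theta + theta_phase[k])
        )
    rho = np.clip(rho, 0.2, None)
    # area of a star region r(theta) = s * rho(theta) is s^2/2 * int rho^2
    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    rho_t = np.ones_like(t)
    for k in range(cfg.mask_harmonics):
        rho_t += (
            cfg.mask_amplitude
            * theta_coeff[k]
            / (k + 1)
            * np.cos((k + 1) * t + theta_phase[k])
        )
    rho_t = np.clip(rho_t, 0.2, None)
    integral = float((rho_t**2).mean() * 2 * np.pi)
    target_area = cfg.mask_area_fraction * frame * frame
    scale = math.sqrt(2.0 * target_area / integral)
    radius = np.hypot(yy - cy, xx - cx)
    mask = radius < scale * rho
    if not mask.any() or mask.all():
        raise ValidationError("degenerate mask (area 0 or 1); adjust the config")
    return mask


def make_tumor_phantom(cfg: PhantomConfig) -> GrayscaleROI:
    """A grayscale tumor phantom with its star-convex mask attached.

    The background texture is the spectral noise field scaled to use the
    lower part of the intensity range; inside the mask the configured
    contrast offset is added, so binarization recovers a bright tumor over
    a dark, textured background with sparse bright speckle.
    """
    rng = np.random.default_rng(cfg.seed)
    field = _spectral_field(cfg.frame, cfg.roughness, rng)
    mask = _star_mask(cfg, rng)
    gray = field * (250.0 - cfg.contrast)
    gray = gray + cfg.contrast * mask
    pixels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return GrayscaleROI(pixels=pixels, mask=mask)


@dataclass
class CohortConfig:
    """Two-group cohort with per-feature group means and SDs.

    Defaults mirror the osteosarcoma study design: 12 good / 10 poor
    responders, 3 imaging planes with 2 images each, SFR higher in poor
    responders (0.94 +/- 0.01) than in good responders (0.91 +/- 0.02),
    and all other features drawn identically in both groups.  Covariates:
    age centered on a pediatric median of 13 years, tumor volume spanning
    roughly 85-10,590 cm^3 on a log scale.
    """

    n_good: int = 12
    n_poor: int = 10
    feature_means: dict = field(default_factory=dict)
    replicate_sd_fraction: float = 0.3
    planes: tuple[str, ...] = PLANES
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good < 2 or self.n_poor < 2:
            raise ValidationError("each group needs at least 2 patients")
        defaults = {
            # feature: (mean_good, sd_good, mean_poor, sd_poor)
            "d_bin": (1.80, 0.06, 1.80, 0.06),
            "d_out": (1.25, 0.08, 1.25, 0.08),
            "sfr": (0.91, 0.02, 0.94, 0.01),
            "lambda": (1.15, 0.06, 1.15, 0.06),
            "s_asm": (0.05, 0.015, 0.05, 0.015),
            "s_idm": (0.45, 0.08, 0.45, 0.08),
            "s_cn": (120.0, 30.0, 120.0, 30.0),
            "s_cr": (0.65, 0.10, 0.65, 0.10),
            "s_e": (7.5, 0.7, 7.5, 0.7),
        }
        defaults.update(self.feature_means)
        for name, (mg, sg, mp, sp) in defaults.items():
            if sg <= 0 or sp <= 0:
                raise ValidationError(f"SDs for {name} must be positive")
        self.feature_means = defaults


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(np.rint(rng.lognormal(math.log(13.0), 0.35, n)), 4, 60).astype(int)
    volume = np.exp(rng.uniform(math.log(85.0), math.log(10590.0), n))
    surface = np.exp(rng.uniform(math.log(3.2), math.log(57.7), n))
    gender = rng.choice(["male", "female"], n, p=[0.68, 0.32])
    pattern = rng.choice(["concentric", "longitudinal"], n, p=[0.86, 0.14])
    return pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "tumor_volume": np.round(volume, 1),
            "tumor_surface": np.round(surface, 1),
            "pattern": pattern,
        }
    )


def make_feature_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Feature-tier cohort: per-image feature values drawn directly.

    Each patient receives a latent per-feature value from their group's
    normal distribution; each of the 6 images (3 planes x 2 replicates)
    observes it with within-patient noise of SD
    ``replicate_sd_fraction * group SD``.  Returns a tidy DataFrame with
    one row per image.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    groups = [("good", cfg.n_good, 0), ("poor", cfg.n_poor, cfg.n_good)]
    cov_all = _covariates(cfg.n_good + cfg.n_poor, rng)
    for response, n, offset in groups:
        for k in range(n):
            pid = f"P{offset + k + 1:03d}"
            latent = {}
            for name, params in cfg.feature_means.items():
                mean, sd = (params[0], params[1]) if response == "good" else (
                    params[2],
                    params[3],
                )
                latent[name] = (rng.normal(mean, sd), sd)
            cov = cov_all.iloc[offset + k]
            for plane in cfg.planes:
                for rep in range(1, cfg.replicates + 1):
                    row = {
                        "patient_id": pid,
                        "response": response,
                        "plane": plane,
                        "replicate": rep,
                        "image_id": f"{pid}_{plane}_{rep}",
                        **cov.to_dict(),
                    }
                    for name, (mu, sd) in latent.items():
                        row[name] = rng.normal(
                            mu, cfg.replicate_sd_fraction * sd
                        )
                    rows.append(row)
    return pd.DataFrame(rows)


# cache of SFR-vs-area-fraction calibration curves, keyed by the phantom
# parameters that affect the mapping
_CALIBRATION_CACHE: dict = {}


def _sfr_calibration(
    frame: int,
    roughness: float,
    contrast: float,
    grid: tuple[float, ...] = (0.06, 0.10, 0.16, 0.24, 0.34, 0.45, 0.55),
    n_seeds: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean measured SFR per mask-area fraction (coarse grid, cached)."""
    key = (frame, round(roughness, 4), round(contrast, 2), grid, n_seeds)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    fcfg = FractalConfig()
    sfrs = []
    for frac in grid:
        vals = []
        for s in range(n_seeds):
            phantom = make_tumor_phantom(
                PhantomConfig(
                    frame=frame,
                    roughness=roughness,
                    mask_area_fraction=frac,
                    contrast=contrast,
                    seed=977 + s,
                )
            )
            vals.append(compute_sfr(phantom, cfg=fcfg))
        sfrs.append(float(np.mean(vals)))
    fracs = np.asarray(grid)
    sfrs = np.asarray(sfrs)
    order = np.argsort(sfrs)
    result = (sfrs[order], fracs[order])
    _CALIBRATION_CACHE[key] = result
    return result


def _area_fraction_for_sfr(
    target_sfr: float, frame: int, roughness: float, contrast: float
) -> float:
    """Invert the calibration curve by linear interpolation."""
    sfrs, fracs = _sfr_calibration(frame, roughness, contrast)
    lo, hi = float(sfrs.min()), float(sfrs.max())
    if not lo - 0.01 <= target_sfr <= hi + 0.01:
        raise ValidationError(
            f"target SFR {target_sfr:.3f} outside the achievable range "
            f"[{lo:.3f}, {hi:.3f}] for frame={frame}, H={roughness}, "
            f"contrast={contrast}"
        )
    return float(np.interp(target_sfr, sfrs, fracs))


def make_image_cohort(
    cfg: CohortConfig,
    out_dir: str | Path,
    frame: int = 128,
    roughness: float = 0.5,
    contrast: float = 140.0,
) -> pd.DataFrame:
    """Image-tier cohort: phantom PNGs + masks + cohort CSV on disk.

    Per patient, a target SFR is drawn from the group distribution and
    translated into a mask-area fraction through the cached calibration
    curve; 6 phantoms (3 planes x 2 replicates) are generated with
    independent seeds and written as ``images/<patient>/<plane>_<rep>.png``
    with masks under ``masks/``.  Returns the cohort table, which is also
    written to ``cohort.csv``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    mg, sg, mp, sp = cfg.feature_means["sfr"]
    cov_all = _covariates(cfg.n_good + cfg.n_poor, rng)
    rows = []
    for response, n, offset in (("good", cfg.n_good, 0), ("poor", cfg.n_poor, cfg.n_good)):
        mean, sd = (mg, sg) if response == "good" else (mp, sp)
        for k in range(n):
            pid = f"P{offset + k + 1:03d}"
            target = rng.normal(mean, sd)
            frac = _area_fraction_for_sfr(target, frame, roughness, contrast)
            (out_dir / "images" / pid).mkdir(exist_ok=True)
            (out_dir / "masks" / pid).mkdir(exist_ok=True)
            cov = cov_all.iloc[offset + k]
            for plane in cfg.planes:
                for rep in range(1, cfg.replicates + 1):
                    seed = int(rng.integers(0, 2**31 - 1))
                    phantom = make_tumor_phantom(
                        PhantomConfig(
                            frame=frame,
                            roughness=roughness,
                            mask_area_fraction=frac,
                            contrast=contrast,
                            seed=seed,
                        )
                    )
                    img_rel = f"images/{pid}/{plane}_{rep}.png"
                    mask_rel = f"masks/{pid}/{plane}_{rep}.png"
                    save_grayscale(phantom, out_dir / img_rel)
                    Image.fromarray(
                        np.where(phantom.mask, 255, 0).astype(np.uint8), mode="L"
                    ).save(out_dir / mask_rel)
                    rows.append(
                        {
                            "patient_id": pid,
                            "response": response,
                            "plane": plane,
                            "replicate": rep,
                            "image": img_rel,
                            "mask": mask_rel,
                            **cov.to_dict(),
                        }
                    )
    cohort = pd.DataFrame(rows)
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    cfg_lines = [
        f"n_good={cfg.n_good}",
        f"n_poor={cfg.n_poor}",
        f"frame={frame}",
        f"roughness={roughness}",
        f"contrast={contrast}",
        f"seed={cfg.seed}",
        f"sfr_targets=good {mg}+/-{sg}, poor {mp}+/-{sp}",
    ]
    (out_dir / "generator_config.txt").write_text("\n".join(cfg_lines) + "\n")
    return cohort


def make_cohort(
    cfg: CohortConfig,
    tier: str = "feature",
    out_dir: str | Path | None = None,
    **image_kwargs,
) -> pd.DataFrame:
    """Dispatch to the feature- or image-tier generator."""
    if tier == "feature":
        return make_feature_cohort(cfg)
    if tier == "image":
        if out_dir is None:
            raise ValidationError("image-tier cohorts need an output directory")
        return make_image_cohort(cfg, out_dir, **image_kwargs)
    raise ValidationError(f"unknown cohort tier {tier!r}")
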