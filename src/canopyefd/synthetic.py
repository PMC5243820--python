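"""Synthetic canopy images and RCBD trait simulations with ground truth.

Shapes are star-convex radial perturbations of an ellipse,

    r(phi) = r_ellipse(phi) * (1 + lobe_amplitude * cos(lobe_count * phi) + noise),

which guarantees a simple closed polygon with analytic/numeric ground
truth, while the lobes emulate leaflet-driven boundary complexity.  The
polygon is rendered as a green blob on brown soil in HSV space, with
optional debris specks (foreground-colored, disjoint) and interior holes
(background-colored).  One seeded generator drives all draws so output is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import color, draw

from canopyefd.morphometrics import TraitVector, compute_traits

__all__ = [
    "CanopyShapeParams",
    "RCBDSimParams",
    "CanopySample",
    "generate_canopy_polygon",
    "generate_canopy_image",
    "generate_fixture_suite",
    "simulate_rcbd_traits",
]

# HSV bands: foreground inside the default segmentation acceptance band
# (green), background outside it (brown soil).
_FG_HUE = (0.24, 0.38)
_FG_SAT = (0.55, 0.85)
_FG_VAL = (0.35, 0.75)
_BG_HUE = (0.05, 0.11)
_BG_SAT = (0.35, 0.60)
_BG_VAL = (0.25, 0.55)


@dataclass(frozen=True)
class CanopyShapeParams:
    semi_axes: tuple[float, float] = (90.0, 70.0)
    lobe_count: int = 0
    lobe_amplitude: float = 0.0
    boundary_noise_sd: float = 0.0
    rotation: float = 0.0
    debris_count: int = 0
    hole_count: int = 0
    image_size: tuple[int, int] = (256, 256)  # (height, width)
    n_vertices: int = 720
    pixel_noise: float = 0.02  # per-pixel HSV jitter amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.lobe_count < 0 or self.debris_count < 0 or self.hole_count < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.lobe_amplitude < 1:
            raise ValueError("lobe_amplitude must be in [0, 1)")
        if self.lobe_amplitude + 3.0 * self.boundary_noise_sd >= 1.0:
            raise ValueError(
                "lobe_amplitude + 3*boundary_noise_sd must stay below 1 "
                "to keep the shape simple"
            )
        h, w = self.image_size
        margin = max(self.semi_axes) * (1 + self.lobe_amplitude + 3 * self.boundary_noise_sd)
        if margin * 2 >= min(h, w):
            raise ValueError("shape does not fit in the image with a safety margin")


@dataclass(frozen=True)
class RCBDSimParams:
    n_genotypes: int = 100
    k: int = 3
    mu: float = 0.0
    sigma2_g: float = 1.0
    sigma2_b: float = 0.0
    sigma2_e: float = 1.0
    seed: int = 0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.n_genotypes < 1 or self.k < 1:
            raise ValueError("need at least one genotype and one block")
        if min(self.sigma2_g, self.sigma2_b, self.sigma2_e) < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class CanopySample:
    image: np.ndarray        # (H, W, 3) uint8 RGB
    mask: np.ndarray         # (H, W) bool ground-truth canopy region (holes filled)
    contour: np.ndarray      # (n, 2) rendered boundary polygon, y-up pixel coords
    traits: TraitVector      # truth traits of the noiseless polygon
    params: CanopyShapeParams


def _radial_polygon(params: CanopyShapeParams, noise: np.ndarray | None) -> np.ndarray:
    """Polygon vertices (x, y_up) around the image center."""
    a, b = params.semi_axes
    h, w = params.image_size
    phi = np.linspace(0.0, 2.0 * np.pi, params.n_vertices, endpoint=False)
    rel = phi - params.rotation
    r_ell = a * b / np.sqrt((b * np.cos(rel)) ** 2 + (a * np.sin(rel)) ** 2)
    mod = 1.0 + params.lobe_amplitude * np.cos(params.lobe_count * phi)
    if noise is not None:
        mod = mod + noise
    r = r_ell * mod
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])


def generate_canopy_polygon(params: CanopyShapeParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """The (noisy) boundary polygon alone, without rendering an image.

    Boundary noise is clipped at +-3 sd so the simplicity invariant of the
    parameter validation also bounds the realized radius.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    noise = None
    if params.boundary_noise_sd > 0:
        raw = rng.normal(0.0, params.boundary_noise_sd, params.n_vertices)
        noise = np.clip(raw, -3 * params.boundary_noise_sd, 3 * params.boundary_noise_sd)
    return _radial_polygon(params, noise)


def _hsv_field(rng, shape, hue, sat, val):
    hsv = np.empty(shape + (3,))
    hsv[..., 0] = rng.uniform(*hue)
    hsv[..., 1] = rng.uniform(*sat)
    hsv[..., 2] = rng.uniform(*val)
    return hsv


def generate_canopy_image(params: CanopyShapeParams) -> CanopySample:
    """Render one canopy sample: RGB image, truth mask, contour, traits.

    The truth mask is the filled polygon (interior holes affect only the
    colors, mirroring the hole-filling step of the real pipeline); truth
    traits come from the noiseless polygon.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    poly = generate_canopy_polygon(params, rng)

    rows = (h - 1) - poly[:, 1]
    cols = poly[:, 0]
    rr, cc = draw.polygon(rows, cols, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True

    # base colors
    hsv = _hsv_field(rng, (h, w), _BG_HUE, _BG_SAT, _BG_VAL)
    hsv[mask] = _hsv_field(rng, (int(mask.sum()),), _FG_HUE, _FG_SAT, _FG_VAL)

    # interior holes: background-colored disks well inside the blob
    cx, cy_row = (w - 1) / 2.0, (h - 1) / 2.0
    r_min = float(min(params.semi_axes)) * (1 - params.lobe_amplitude - 3 * params.boundary_noise_sd)
    for _ in range(params.hole_count):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.1, 0.5) * r_min
        radius = rng.uniform(0.04, 0.10) * r_min
        hr, hc = draw.disk((cy_row - dist * np.sin(ang), cx + dist * np.cos(ang)),
                           radius, shape=(h, w))
        hsv[hr, hc] = _hsv_field(rng, (len(hr),), _BG_HUE, _BG_SAT, _BG_VAL)

    # debris: small foreground-colored specks disjoint from the canopy
    margin = 3
    grown = np.zeros_like(mask)
    grown[max(0, rr.min() - margin):rr.max() + margin + 1,
          max(0, cc.min() - margin):cc.max() + margin + 1] = True
    placed = 0
    attempts = 0
    while placed < params.debris_count and attempts < 200 * max(1, params.debris_count):
        attempts += 1
        radius = rng.uniform(1.5, 3.0)
        r0 = rng.uniform(radius + 1, h - radius - 2)
        c0 = rng.uniform(radius + 1, w - radius - 2)
        dr, dc = draw.disk((r0, c0), radius, shape=(h, w))
        if len(dr) == 0 or grown[dr, dc].any():
            continue
        hsv[dr, dc] = _hsv_field(rng, (len(dr),), _FG_HUE, _FG_SAT, _FG_VAL)
        grown[max(0, dr.min() - margin):dr.max() + margin + 1,
              max(0, dc.min() - margin):dc.max() + margin + 1] = True
        placed += 1
    if placed < params.debris_count:
        raise RuntimeError("could not place all debris specks; enlarge the image")

    if params.pixel_noise > 0:
        hsv[..., 1:] += rng.uniform(-params.pixel_noise, params.pixel_noise, (h, w, 2))
        hsv[..., 0] += rng.uniform(-params.pixel_noise / 4, params.pixel_noise / 4, (h, w))
        hsv = np.clip(hsv, 0.0, 1.0)

    image = (color.hsv2rgb(hsv) * 255).round().astype(np.uint8)

    noiseless = _radial_polygon(params, None)
    truth_traits = compute_traits(noiseless)
    return CanopySample(image=image, mask=mask, contour=poly, traits=truth_traits, params=params)


def _suite_params(n: int, seed: int, image_size: tuple[int, int]) -> list[CanopyShapeParams]:
    """A complexity gradient from a circle to a designated high-lobe star."""
    rng = np.random.default_rng(seed)
    h, w = image_size
    base = 0.30 * min(h, w)
    out = []
    for i in range(n):
        frac = i / max(1, n - 1)
        if i == 0:
            lobes, amp = 0, 0.0
        elif i == n - 1:
            lobes, amp = 12, 0.25  # designated most complex
        else:
            lobes = int(round(2 + frac * 8))
            amp = 0.04 + 0.16 * frac
        ecc = rng.uniform(0.6, 1.0)
        out.append(CanopyShapeParams(
            semi_axes=(base, base * ecc),
            lobe_count=lobes,
            lobe_amplitude=amp,
            boundary_noise_sd=0.0,
            rotation=float(rng.uniform(0, np.pi)),
            debris_count=int(rng.integers(0, 4)) if 0 < i < n - 1 else 0,
            hole_count=int(rng.integers(0, 3)) if 0 < i < n - 1 else 0,
            image_size=image_size,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out


def generate_fixture_suite(
    out_dir,
    n: int = 20,
    seed: int = 0,
    image_size: tuple[int, int] = (400, 400),
) -> pd.DataFrame:
    """Write n canopy images spanning a complexity gradient, plus truth.

    Produces ``canopy_###.png`` images, ``mask_###.png`` truth masks,
    ``contour_###.csv`` truth outlines, and ``manifest.csv`` with one row
    per image (id, paths, parameters, truth traits, most_complex flag).
    The last image is the designated most complex (12-lobe) shape.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, params in enumerate(_suite_params(n, seed, image_size)):
        sample = generate_canopy_image(params)
        img_path = out_dir / f"canopy_{i:03d}.png"
        mask_path = out_dir / f"mask_{i:03d}.png"
        contour_path = out_dir / f"contour_{i:03d}.csv"
        iio.imwrite(img_path, sample.image)
        iio.imwrite(mask_path, (sample.mask.astype(np.uint8) * 255))
        pd.DataFrame({
            "point_index": np.arange(len(sample.contour)),
            "x": sample.contour[:, 0],
            "y": sample.contour[:, 1],
        }).to_csv(contour_path, index=False, float_format="%.17g")
        rows.append({
            "id": f"canopy_{i:03d}",
            "image": img_path.name,
            "mask": mask_path.name,
            "contour": contour_path.name,
            "most_complex": i == n - 1,
            "params": json.dumps(asdict(params)),
            **{f"truth_{k}": v for k, v in sample.traits.as_dict().items()},
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.17g")
    return manifest


def simulate_rcbd_traits(params: RCBDSimParams) -> pd.DataFrame:
    """Simulate a balanced RCBD trait table y = mu + g_i + b_k + e_ik.

    Genotype, block, and residual effects are independent normals with the
    requested variances; the output is a long table with columns
    genotype, block, trait, value.
    """
    rng = np.random.default_rng(params.seed)
    g = rng.normal(0.0, np.sqrt(params.sigma2_g), params.n_genotypes)
    b = rng.normal(0.0, np.sqrt(params.sigma2_b), params.k)
    e = rng.normal(0.0, np.sqrt(params.sigma2_e), (params.n_genotypes, params.k))
    y = params.mu + g[:, None] + b[None, :] + e
    gi, bk = np.meshgrid(np.arange(params.n_genotypes), np.arange(params.k), indexing="ij")
    return pd.DataFrame({
        "genotype": [f"g{i:04d}" for i in gi.ravel()],
        "block": [f"b{k}" for k in bk.ravel()],
        "trait": params.trait,
        "value": y.ravel(),
    })
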