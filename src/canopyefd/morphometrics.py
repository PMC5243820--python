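"""Traditional morphometric traits of closed contours.

Traits are computed on the polygon traced by the contour (original or
EFD-reconstructed), so fidelity comparisons between the two are
apples-to-apples:

* aspect ratio — major/minor axis of the moment-equivalent ellipse
* roundness   — 4*Area / (pi * major_axis^2)
* circularity — 4*pi*Area / Perimeter^2 (isoperimetric ratio)
* solidity    — Area / ConvexArea

The ellipse is the one with the same normalized second central moments as
the polygon region, the convention used by common image-analysis tools.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from canopyefd.efd import EFDSet, chain_code, reconstruct_contour

__all__ = [
    "EllipseFit",
    "TraitVector",
    "fit_ellipse",
    "compute_traits",
    "traits_from_efd",
    "trait_fidelity",
]

TRAIT_NAMES = ("aspect_ratio", "roundness", "circularity", "solidity")


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a polygon region (major >= minor)."""

    major_axis: float
    minor_axis: float
    center: tuple[float, float]
    orientation: float  # radians, angle of the major axis to +x, in (-pi/2, pi/2]


@dataclass(frozen=True)
class TraitVector:
    aspect_ratio: float
    roundness: float
    circularity: float
    solidity: float
    area: float
    perimeter: float
    convex_area: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _polygon_moments(pts: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Signed area, centroid, and per-area second central moments of a polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    ixx = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    iyy = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    # central per-area second moments (covariance of the uniform region)
    mxx = ixx / area - cx * cx
    myy = iyy / area - cy * cy
    mxy = ixy / area - cx * cy
    return area, cx, cy, mxx, myy, mxy


def fit_ellipse(contour: np.ndarray) -> EllipseFit:
    """Ellipse with the same normalized second central moments as the polygon."""
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("contour must be an (n>=5, 2) point array")
    area, cx, cy, mxx, myy, mxy = _polygon_moments(pts)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[0] <= 0:
        raise ValueError("degenerate (collinear) contour")
    minor = 4.0 * np.sqrt(eigvals[0])
    major = 4.0 * np.sqrt(eigvals[1])
    vx, vy = eigvecs[:, 1]
    orientation = np.arctan2(vy, vx)
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    return EllipseFit(
        major_axis=float(major), minor_axis=float(minor),
        center=(float(cx), float(cy)), orientation=float(orientation),
    )


def compute_traits(contour: np.ndarray) -> TraitVector:
    """Compute the four traits plus area/perimeter/convex-area intermediates.

    Area is the absolute shoelace area of the contour polygon, perimeter the
    summed segment lengths (including the closing segment), convex area the
    area of the contour's convex hull.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("contour must be an (n>=5, 2) point array")
    area, *_ = _polygon_moments(pts)
    area = abs(area)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    perimeter = float(np.hypot(d[:, 0], d[:, 1]).sum())
    hull = ConvexHull(pts)
    convex_area = float(hull.volume)  # 2-D hull: volume is the area
    ellipse = fit_ellipse(pts)
    return TraitVector(
        aspect_ratio=ellipse.major_axis / ellipse.minor_axis,
        roundness=4.0 * area / (np.pi * ellipse.major_axis**2),
        circularity=4.0 * np.pi * area / perimeter**2,
        solidity=area / convex_area,
        area=float(area),
        perimeter=perimeter,
        convex_area=convex_area,
    )


def traits_from_efd(efd: EFDSet, n_harmonics: int, n_points: int = 512) -> TraitVector:
    """Traits of the N-harmonic reconstruction sampled uniformly in arc length."""
    t = np.linspace(0.0, efd.T, n_points, endpoint=False)
    return compute_traits(reconstruct_contour(efd, n_harmonics, t))


def trait_fidelity(
    contours,
    efds,
    n_harmonics: int,
    ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare traits from original contours and their EFD reconstructions.

    For every canopy the reconstruction is evaluated at the original vertex
    arc lengths, and the four traits are computed from both polygons.

    Returns
    -------
    table : DataFrame
        One row per canopy and source ('original' / 'reconstructed').
    summary : DataFrame
        Per-trait Pearson correlation and maximum relative deviation.
    """
    contours, efds = list(contours), list(efds)
    if len(contours) != len(efds):
        raise ValueError("contours and EFD records are not aligned")
    if ids is None:
        ids = list(range(len(contours)))
    ids = list(ids)
    if len(ids) != len(contours):
        raise ValueError("ids not aligned with contours")

    rows = []
    for cid, contour, efd in zip(ids, contours, efds):
        chain = chain_code(contour)
        t_orig = np.concatenate([[0.0], chain.t[:-1]])
        reco = reconstruct_contour(efd, n_harmonics, t_orig)
        rows.append({"id": cid, "source": "original", **compute_traits(chain.points).as_dict()})
        rows.append({"id": cid, "source": "reconstructed", **compute_traits(reco).as_dict()})
    table = pd.DataFrame(rows)

    orig = table[table.source == "original"].set_index("id")
    reco = table[table.source == "reconstructed"].set_index("id")
    summary_rows = []
    for trait in TRAIT_NAMES:
        o, r = orig[trait].to_numpy(), reco[trait].to_numpy()
        corr = float(np.corrcoef(o, r)[0, 1]) if len(o) > 1 and np.std(o) > 0 else np.nan
        max_rel_dev = float(np.max(np.abs(r - o) / np.abs(o)))
        summary_rows.append({"trait": trait, "correlation": corr, "max_rel_dev": max_rel_dev})
    return table, pd.DataFrame(summary_rows)
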