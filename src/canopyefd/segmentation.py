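"""Foreground segmentation of canopy photographs and outline extraction.

The stage mirrors a standard plot-photo workflow: HSV thresholding to
separate plant pixels from soil, largest-connected-component cleanup,
hole filling, and Moore-neighbor boundary tracing of the filled blob.

Coordinate convention
---------------------
Images are indexed ``(row, col)`` with row 0 at the top.  Contours are
reported as ``(x, y)`` points with ``x = col`` and ``y = (height - 1) - row``
(y grows upward), so that all downstream polygon/EFD math lives in a
conventional right-handed plane.  Outer contours are traced
counter-clockwise in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, measure

__all__ = [
    "SegmentationConfig",
    "segment_foreground",
    "clean_mask",
    "fill_holes",
    "extract_outline",
]


def _normalize_hue(h: float) -> float:
    """Map a hue given in degrees (value > 1) onto the unit interval."""
    h = float(h)
    if h > 1.0:
        h = h / 360.0
    if not 0.0 <= h < 1.0 + 1e-12:
        raise ValueError(f"hue {h} outside [0, 1) after normalization")
    return h % 1.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for HSV foreground segmentation.

    Parameters
    ----------
    hue_min, hue_max : float
        Accepted hue band, either in [0, 1) or in degrees.  The band is
        circular: ``hue_min > hue_max`` means the band wraps through the
        hue origin.
    saturation_min : float
        Minimum saturation for a foreground pixel, in [0, 1].
    min_component_fraction : float
        Components smaller than this fraction of the largest one are always
        removed by :func:`clean_mask`.  The default of 1.0 keeps only the
        single largest component, matching the plot-isolation step.
    """

    hue_min: float = 0.15
    hue_max: float = 0.50
    saturation_min: float = 0.25
    min_component_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hue_min", _normalize_hue(self.hue_min))
        object.__setattr__(self, "hue_max", _normalize_hue(self.hue_max))
        if not 0.0 <= self.saturation_min <= 1.0:
            raise ValueError("saturation_min must be in [0, 1]")
        if not 0.0 < self.min_component_fraction <= 1.0:
            raise ValueError("min_component_fraction must be in (0, 1]")

    def hue_in_band(self, hue: np.ndarray) -> np.ndarray:
        """Circular membership test for an array of hues in [0, 1)."""
        hue = np.asarray(hue)
        if self.hue_min <= self.hue_max:
            return (hue >= self.hue_min) & (hue <= self.hue_max)
        return (hue >= self.hue_min) | (hue <= self.hue_max)


def segment_foreground(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Threshold an RGB image in HSV space.

    A pixel is foreground iff its saturation is at least
    ``config.saturation_min`` and its hue falls inside the configured band.
    No morphological operation is applied here.

    Parameters
    ----------
    image : (H, W, 3) array
        8-bit or float RGB image.
    config : SegmentationConfig, optional
        Defaults accept green-through-yellow hues.

    Returns
    -------
    (H, W) boolean mask.
    """
    if config is None:
        config = SegmentationConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3 or image.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) RGB image")
    hsv = color.rgb2hsv(image)
    hue, sat = hsv[..., 0], hsv[..., 1]
    return (sat >= config.saturation_min) & config.hue_in_band(hue)


def clean_mask(mask: np.ndarray, min_component_fraction: float = 1.0) -> np.ndarray:
    """Keep the largest 8-connected foreground component.

    Ties between equal-size components are broken deterministically by
    keeping the component containing the earliest pixel in row-major order.
    With ``min_component_fraction < 1`` every component at least that
    fraction of the largest is retained as well (escape hatch for
    multi-blob plots; the default mirrors single-plot isolation).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 1:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest_size = sizes.max()
    if min_component_fraction < 1.0:
        keep = np.flatnonzero(sizes >= min_component_fraction * largest_size)
        return np.isin(labels, keep)
    # tie-break: label() assigns labels in row-major scan order, so among
    # equal-size components the smallest label holds the earliest pixel
    winner = int(np.flatnonzero(sizes == largest_size)[0])
    return labels == winner


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    return ndimage.binary_fill_holes(mask)


# clockwise Moore neighborhood in image coords (y down), starting at West
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def extract_outline(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a filled single-component mask.

    Uses Moore-neighbor tracing with Jacob's stopping criterion.  The first
    contour point is the boundary pixel first encountered in row-major
    scan; consecutive points are 8-neighbors; the loop is returned
    counter-clockwise in the y-up ``(x, y)`` frame.

    Returns
    -------
    (n, 2) float array of ``(x, y)`` points, ``n >= 3``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    h, w = mask.shape
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))

    # West neighbor of the row-major-first pixel is guaranteed background.
    cur = start
    b_idx = 0
    boundary = [start]
    seen = {(start, 0)}
    while True:
        nxt = None
        for k in range(1, 9):
            j = (b_idx + k) % 8
            cand = (cur[0] + _MOORE[j][0], cur[1] + _MOORE[j][1])
            if padded[cand]:
                prev = (cur[0] + _MOORE[(j - 1) % 8][0], cur[1] + _MOORE[(j - 1) % 8][1])
                nxt = cand
                new_b = _MOORE_INDEX[(prev[0] - cand[0], prev[1] - cand[1])]
                break
        if nxt is None:  # isolated pixel
            break
        if (nxt, new_b) in seen:
            break
        seen.add((nxt, new_b))
        boundary.append(nxt)
        cur, b_idx = nxt, new_b

    if len(boundary) < 3:
        raise ValueError("degenerate blob: fewer than 3 boundary pixels")

    pts = np.asarray(boundary, dtype=float)
    xy = np.column_stack([pts[:, 1] - 1.0, (h - 1.0) - (pts[:, 0] - 1.0)])
    # enforce counter-clockwise orientation in the y-up frame
    x, y = xy[:, 0], xy[:, 1]
    signed2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed2 < 0:
        xy = np.vstack([xy[:1], xy[1:][::-1]])
    return xy
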