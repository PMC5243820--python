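"""Elliptic Fourier descriptors of closed contours.

A closed contour is chain coded into per-step displacements and Euclidean
step lengths (1 or sqrt(2) on pixel chains, arbitrary on analytic
polygons), expanded into harmonic coefficient quadruples (a_n, b_n, c_n,
d_n) plus the two DC terms (A0, C0), truncated by a reconstruction-error
criterion, and standardized to be invariant to size, rotation, and
starting point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChainCodedContour",
    "EFDSet",
    "StandardizedEFD",
    "HarmonicSelection",
    "chain_code",
    "elliptic_fourier_coefficients",
    "reconstruct_contour",
    "deviation_error",
    "reconstruction_error",
    "find_most_complex",
    "select_n_harmonics",
    "standardize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainCodedContour:
    """Chain-coded closed contour.

    ``points`` holds the s original vertices; step i (i = 1..s) joins
    vertex i-1 to vertex i, with vertex s wrapping to vertex 0.  ``t`` is
    the cumulative arc length after each step, so ``t[-1] == perimeter``.
    """

    points: np.ndarray  # (s, 2) original vertices (x, y)
    dx: np.ndarray      # (s,) per-step displacement along x
    dy: np.ndarray      # (s,) per-step displacement along y
    dt: np.ndarray      # (s,) per-step Euclidean length
    t: np.ndarray       # (s,) cumulative arc length, t[-1] == T

    @property
    def perimeter(self) -> float:
        return float(self.t[-1])

    @property
    def n_steps(self) -> int:
        return len(self.dt)


@dataclass(frozen=True)
class EFDSet:
    """Elliptic Fourier descriptor record: DC terms plus 4N coefficients."""

    A0: float
    C0: float
    coeffs: np.ndarray  # (N, 4) columns a_n, b_n, c_n, d_n
    T: float            # contour perimeter (sets the parameter period)

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class StandardizedEFD:
    """Size/rotation/start-point invariant coefficients plus the frame.

    The frame records how the raw record was normalized: ``L`` the
    semi-major axis of the first-harmonic ellipse, ``psi`` its angle to the
    +x axis, ``theta = 2 pi t_m / T`` the start-point phase, the ellipse
    center ``(A0, C0)`` and the modified start point ``(xm, ym)`` on the
    major axis.  After standardization a_1* = 1, b_1* = 0, c_1* = 0.
    """

    coeffs: np.ndarray  # (N, 4) standardized quadruples
    L: float
    psi: float
    theta: float
    A0: float
    C0: float
    xm: float
    ym: float

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class HarmonicSelection:
    """Result of the harmonic-count sweep."""

    n: int
    converged: bool
    sweep: np.ndarray = field(repr=False)   # swept harmonic counts
    errors: np.ndarray = field(repr=False)  # percent error at each count


def chain_code(contour: np.ndarray) -> ChainCodedContour:
    """Chain code a closed contour.

    Works for both integer pixel chains (steps restricted to the 8
    Freeman directions, lengths 1 or sqrt(2)) and analytic polygons (any
    non-zero step; the contour is treated as piecewise linear).  The
    closing step from the last vertex back to the first is included.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must be an (n>=3, 2) point array")
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        raise ValueError("contour contains immediately repeated points")
    if np.allclose(pts, np.round(pts)):
        if np.any(np.abs(d) > 1 + 1e-9):
            raise ValueError("pixel chain has non-8-adjacent consecutive points")
    return ChainCodedContour(points=pts, dx=d[:, 0], dy=d[:, 1], dt=dt, t=np.cumsum(dt))


def _phases(chain: ChainCodedContour, n_harmonics: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angles 2*pi*n*t_p/T for p = 0..s and n = 1..N, plus cos/sin diffs."""
    T = chain.perimeter
    t_full = np.concatenate([[0.0], chain.t])  # t_0 = 0 through t_s = T
    n = np.arange(1, n_harmonics + 1, dtype=float)
    ang = (2.0 * np.pi / T) * np.outer(n, t_full)  # (N, s+1)
    dcos = np.diff(np.cos(ang), axis=1)  # (N, s)
    dsin = np.diff(np.sin(ang), axis=1)
    return n, dcos, dsin


def elliptic_fourier_coefficients(chain: ChainCodedContour, n_harmonics: int) -> EFDSet:
    """Compute the EFD record of a chain-coded contour.

    The harmonic quadruples follow the classical closed-contour expansion
    (sums over the chain steps of slope times cosine/sine increments); the
    DC terms (A0, C0) are the arc-length averages of the piecewise-linear
    coordinate functions, i.e. the center of the first-harmonic ellipse.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    T = chain.perimeter
    if T <= 0:
        raise ValueError("contour has zero perimeter")
    n, dcos, dsin = _phases(chain, n_harmonics)
    vx = chain.dx / chain.dt  # slope of x(t) on each step
    vy = chain.dy / chain.dt
    scale = T / (2.0 * n**2 * np.pi**2)
    a = scale * (dcos @ vx)
    b = scale * (dsin @ vx)
    c = scale * (dcos @ vy)
    d = scale * (dsin @ vy)

    # DC terms: arc-length mean of x(t), y(t) over the closed polygon
    closed = np.vstack([chain.points, chain.points[:1]])
    seg_mean = 0.5 * (closed[:-1] + closed[1:])
    A0, C0 = (chain.dt @ seg_mean) / T
    return EFDSet(A0=float(A0), C0=float(C0), coeffs=np.column_stack([a, b, c, d]), T=T)


def reconstruct_contour(efd: EFDSet, n_harmonics: int, t_values: np.ndarray) -> np.ndarray:
    """Evaluate the truncated Fourier series at given arc-length positions.

    Returns an (len(t_values), 2) array of (x, y) points.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics > efd.n_harmonics:
        raise ValueError(
            f"requested {n_harmonics} harmonics but only {efd.n_harmonics} stored"
        )
    t = np.asarray(t_values, dtype=float)
    n = np.arange(1, n_harmonics + 1, dtype=float)
    ang = (2.0 * np.pi / efd.T) * np.outer(n, t)  # (N, P)
    cos_m, sin_m = np.cos(ang), np.sin(ang)
    a, b, c, d = (efd.coeffs[:n_harmonics, i] for i in range(4))
    x = efd.A0 + a @ cos_m + b @ sin_m
    y = efd.C0 + c @ cos_m + d @ sin_m
    return np.column_stack([x, y])


def first_harmonic_semi_major(efd: EFDSet) -> float:
    """Semi-major axis length L of the first-harmonic ellipse.

    Equals the largest singular value of [[a1, b1], [c1, d1]].
    """
    m = efd.coeffs[0].reshape(2, 2)
    return float(np.linalg.svd(m, compute_uv=False)[0])


def deviation_error(original: np.ndarray, reconstructed: np.ndarray, semi_major: float) -> float:
    """Percent deviation: max pointwise Euclidean distance over 2L, x100.

    Points are paired positionally (the reconstruction is expected to be
    evaluated at the original arc-length parameters).
    """
    if semi_major <= 0:
        raise ValueError("degenerate first harmonic (L = 0)")
    orig = np.asarray(original, dtype=float)
    reco = np.asarray(reconstructed, dtype=float)
    if orig.shape != reco.shape:
        raise ValueError("original and reconstructed point sets differ in shape")
    dist = np.hypot(*(orig - reco).T)
    return float(dist.max() / (2.0 * semi_major) * 100.0)


def reconstruction_error(chain: ChainCodedContour, efd: EFDSet, n_harmonics: int) -> float:
    """Percent error of the N-harmonic reconstruction of a chain's contour.

    The reconstruction is evaluated at the original vertex arc lengths
    (pointwise correspondence) and the maximum Euclidean deviation is
    normalized by the full major-axis length (2L) of the first-harmonic
    ellipse.
    """
    t_orig = np.concatenate([[0.0], chain.t[:-1]])  # parameters of vertices 0..s-1
    reco = reconstruct_contour(efd, n_harmonics, t_orig)
    return deviation_error(chain.points, reco, first_harmonic_semi_major(efd))


def _error_sweep(chain: ChainCodedContour, sweep: np.ndarray) -> np.ndarray:
    """Reconstruction error at each harmonic count of a sweep.

    Shares one coefficient computation at max(sweep) and accumulates
    per-harmonic reconstruction contributions, so the full sweep costs one
    O(N_max * s) pass.
    """
    n_max = int(sweep.max())
    efd = elliptic_fourier_coefficients(chain, n_max)
    L = first_harmonic_semi_major(efd)
    if L <= 0:
        raise ValueError("degenerate first harmonic (L = 0)")
    t_orig = np.concatenate([[0.0], chain.t[:-1]])
    n = np.arange(1, n_max + 1, dtype=float)
    ang = (2.0 * np.pi / efd.T) * np.outer(n, t_orig)
    cos_m, sin_m = np.cos(ang), np.sin(ang)
    a, b, c, d = (efd.coeffs[:, i][:, None] for i in range(4))
    x_cum = efd.A0 + np.cumsum(a * cos_m + b * sin_m, axis=0)  # (N, P)
    y_cum = efd.C0 + np.cumsum(c * cos_m + d * sin_m, axis=0)
    idx = sweep - 1
    dist = np.hypot(x_cum[idx] - chain.points[:, 0], y_cum[idx] - chain.points[:, 1])
    return dist.max(axis=1) / (2.0 * L) * 100.0


def find_most_complex(contours, probe_n: int = 10) -> int:
    """Index of the contour with the largest probe-harmonic reconstruction error.

    Ties are broken by the lowest index.
    """
    contours = list(contours)
    if not contours:
        raise ValueError("empty contour collection")
    errors = []
    for contour in contours:
        chain = contour if isinstance(contour, ChainCodedContour) else chain_code(contour)
        efd = elliptic_fourier_coefficients(chain, probe_n)
        errors.append(reconstruction_error(chain, efd, probe_n))
    return int(np.argmax(errors))


def select_n_harmonics(
    contour,
    threshold_pct: float = 1.0,
    sweep_min: int = 10,
    sweep_max: int = 1000,
    sweep_step: int = 10,
) -> HarmonicSelection:
    """Smallest swept harmonic count with reconstruction error <= threshold.

    If no count in the sweep meets the threshold, the sweep maximum is
    returned with ``converged=False`` (and a warning), so batch runs
    complete.
    """
    if threshold_pct < 0:
        raise ValueError("threshold_pct must be >= 0")
    sweep = np.arange(sweep_min, sweep_max + 1, sweep_step, dtype=int)
    if sweep.size == 0:
        raise ValueError("empty harmonic sweep")
    chain = contour if isinstance(contour, ChainCodedContour) else chain_code(contour)
    errors = _error_sweep(chain, sweep)
    ok = np.flatnonzero(errors <= threshold_pct)
    if ok.size:
        i = int(ok[0])
        return HarmonicSelection(n=int(sweep[i]), converged=True, sweep=sweep, errors=errors)
    logger.warning(
        "harmonic sweep did not reach %.3g%% (best %.3g%% at N=%d); using sweep max",
        threshold_pct, errors.min(), int(sweep[np.argmin(errors)]),
    )
    return HarmonicSelection(n=int(sweep[-1]), converged=False, sweep=sweep, errors=errors)


def _rotate_coeffs(coeffs: np.ndarray, theta: float, psi: float, L: float) -> np.ndarray:
    """Two-sided rotation and scaling of all harmonic quadruples.

    Harmonic n is mapped to (1/L) R(psi) [a b; c d] S(n*theta) where R is
    the row (orientation) rotation and S the column (start-point phase)
    rotation.
    """
    n_h = coeffs.shape[0]
    out = np.empty_like(coeffs)
    cp, sp = math.cos(psi), math.sin(psi)
    left = np.array([[cp, sp], [-sp, cp]])
    for k in range(n_h):
        ang = (k + 1) * theta
        ct, st = math.cos(ang), math.sin(ang)
        right = np.array([[ct, -st], [st, ct]])
        out[k] = (left @ coeffs[k].reshape(2, 2) @ right).ravel() / L
    return out


def _first_significant_even(coeffs: np.ndarray, tol: float = 1e-7) -> float:
    """First even-harmonic coefficient with magnitude above tol, else 0.

    Scanned in (a, b, c, d) order per harmonic; used as a deterministic
    tie-break between the two valid start-point phases (which differ only
    in the sign of even harmonics).
    """
    for k in range(1, coeffs.shape[0], 2):  # harmonics 2, 4, ...
        for v in coeffs[k]:
            if abs(v) > tol:
                return float(v)
    return 0.0


def standardize(efd: EFDSet) -> StandardizedEFD:
    """Make an EFD record invariant to size, rotation, and start point.

    The start-point phase theta places the contour parameter origin on the
    major axis of the first-harmonic ellipse; the orientation psi rotates
    that axis onto +x; 1/L scales the semi-major axis to 1.  The result
    satisfies a_1* = 1, b_1* = 0, c_1* = 0.  Reflection is never applied,
    so mirrored shapes standardize to different records (chirality is
    preserved; the sign of d_1* records it).

    The phase is defined modulo pi; of the two valid solutions (which
    differ by the sign of every even harmonic) the one whose first
    significant even-harmonic coefficient is positive is returned, making
    the normal form unique and idempotent.
    """
    a1, b1, c1, d1 = efd.coeffs[0]
    if np.allclose([a1, b1, c1, d1], 0.0):
        raise ValueError("degenerate first harmonic (L = 0)")

    theta = 0.5 * math.atan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    # candidate axis at phase theta; ensure it is the major axis
    ax = a1 * math.cos(theta) + b1 * math.sin(theta)
    cx = c1 * math.cos(theta) + d1 * math.sin(theta)
    bx = -a1 * math.sin(theta) + b1 * math.cos(theta)
    dx = -c1 * math.sin(theta) + d1 * math.cos(theta)
    if ax * ax + cx * cx < bx * bx + dx * dx:
        theta += 0.5 * math.pi
        ax = a1 * math.cos(theta) + b1 * math.sin(theta)
        cx = c1 * math.cos(theta) + d1 * math.sin(theta)
    L = math.hypot(ax, cx)
    if L <= 0:
        raise ValueError("degenerate first harmonic (L = 0)")
    psi = math.atan2(cx, ax)

    star = _rotate_coeffs(efd.coeffs, theta, psi, L)
    # alternative phase theta + pi: flips the sign of even harmonics only
    flip = np.ones(star.shape[0])
    flip[1::2] = -1.0
    lead = _first_significant_even(star)
    if lead < 0:
        star = star * flip[:, None]
        theta += math.pi
        psi += math.pi
        ax, cx = -ax, -cx  # start point moves to the other major-axis end

    theta %= 2.0 * math.pi
    psi = math.atan2(math.sin(psi), math.cos(psi))
    xm = efd.A0 + ax
    ym = efd.C0 + cx
    return StandardizedEFD(
        coeffs=star, L=L, psi=psi, theta=theta,
        A0=efd.A0, C0=efd.C0, xm=float(xm), ym=float(ym),
    )
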