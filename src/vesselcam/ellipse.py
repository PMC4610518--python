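"""Ellipse reconstruction from a partial liquid-contact arc.

The camera sees only one side of the elliptical liquid surface.  The visible
arc is completed by point-reflecting a copy of it to stand in for the hidden
side, an ellipse is fitted to the combined point set by algebraic least
squares on the general conic

    A x^2 + B xy + C y^2 + D x + E y + F = 0,

and the pixel-level measurements (tangent row, area) are read off the
geometric parameters.

Coordinate convention: ``x`` is the column index, ``y`` the row index,
origin at the top-left pixel, rows increasing downward.  ``level_px`` is
measured from the *bottom* image edge (``rows - y_top``) so that a fuller
glass yields a larger level, matching the calibration-table convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EllipseParams",
    "Measurement",
    "mirror_segment",
    "fit_ellipse",
    "measure",
    "ellipse_from_conic",
    "sample_ellipse",
]


@dataclass(frozen=True)
class EllipseParams:
    """Conic plus geometric description of an ellipse in pixel coordinates."""

    conic: tuple[float, float, float, float, float, float]  # (A, B, C, D, E, F)
    center: tuple[float, float]  # (cx, cy) px
    semi_major: float  # px
    semi_minor: float  # px
    tilt: float  # radians, angle of the major axis from the +x axis

    def __post_init__(self) -> None:
        A, B, C, *_ = self.conic
        if B * B - 4 * A * C >= 0:
            raise ValueError("conic does not describe an ellipse (B^2-4AC >= 0)")
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("semi-axes must satisfy semi_major >= semi_minor > 0")

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    def vertical_half_extent(self) -> float:
        """Half the vertical (row-direction) extent of the tilted ellipse.

        For an ellipse with semi-axes (a, b) and tilt t the extreme y values
        of the boundary lie at cy +/- sqrt(a^2 sin^2 t + b^2 cos^2 t).
        """
        a, b, t = self.semi_major, self.semi_minor, self.tilt
        return float(np.hypot(a * np.sin(t), b * np.cos(t)))

    def horizontal_half_extent(self) -> float:
        a, b, t = self.semi_major, self.semi_minor, self.tilt
        return float(np.hypot(a * np.cos(t), b * np.sin(t)))


@dataclass(frozen=True)
class Measurement:
    """Pixel-space measurement of the reconstructed liquid surface."""

    level_px: float  # rows - y_top, from the bottom image edge
    area_px2: float  # pi * a * b

    def __post_init__(self) -> None:
        if self.area_px2 <= 0:
            raise ValueError("area_px2 must be positive")


def _geometric_from_conic(A, B, C, D, E, F):
    """Center, semi-axes and tilt of the conic; None if not a real ellipse."""
    if B * B - 4 * A * C >= 0:
        return None
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    try:
        cx, cy = np.linalg.solve(2.0 * M, [-D, -E])
    except np.linalg.LinAlgError:
        return None
    # conic value at the center; axes^2 = -Fc / eigenvalues
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    w, V = np.linalg.eigh(M)
    with np.errstate(divide="ignore", invalid="ignore"):
        ax2 = -Fc / w
    if np.any(~np.isfinite(ax2)) or np.any(ax2 <= 0):
        return None
    axes = np.sqrt(ax2)
    i_major = int(np.argmax(axes))
    a, b = float(axes[i_major]), float(axes[1 - i_major])
    tilt = float(np.arctan2(V[1, i_major], V[0, i_major]))
    # canonical tilt in (-pi/2, pi/2]
    if tilt > np.pi / 2:
        tilt -= np.pi
    elif tilt <= -np.pi / 2:
        tilt += np.pi
    return (float(cx), float(cy)), a, b, tilt


def ellipse_from_conic(conic) -> EllipseParams | None:
    """Build :class:`EllipseParams` from conic coefficients, or ``None``."""
    A, B, C, D, E, F = (float(v) for v in conic)
    geo = _geometric_from_conic(A, B, C, D, E, F)
    if geo is None:
        return None
    center, a, b, tilt = geo
    return EllipseParams(conic=(A, B, C, D, E, F), center=center,
                         semi_major=a, semi_minor=b, tilt=tilt)


def sample_ellipse(params: EllipseParams, n: int = 64,
                   theta: np.ndarray | None = None) -> np.ndarray:
    """Points on the ellipse boundary, shape (n, 2) as (x, y)."""
    if theta is None:
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    a, b, t = params.semi_major, params.semi_minor, params.tilt
    cx, cy = params.center
    ct, st = np.cos(t), np.sin(t)
    xe, ye = a * np.cos(theta), b * np.sin(theta)
    return np.column_stack([cx + ct * xe - st * ye, cy + st * xe + ct * ye])


def mirror_segment(columns: np.ndarray, rows: np.ndarray, bottom_offset: float,
                   image_shape: tuple[int, int]) -> np.ndarray:
    """Complete a one-sided arc by point reflection through its centroid.

    The copy is rotated 180 degrees about the arc centroid (which preserves
    the column extent) and then translated vertically so that its lowest
    point sits ``bottom_offset`` rows above the bottom image edge -- the
    fixed-offset reconstruction rule of the measurement procedure.

    Returns the stacked (2N, 2) point set as (x=col, y=row).
    """
    columns = np.asarray(columns, dtype=float)
    rows = np.asarray(rows, dtype=float)
    if columns.size == 0:
        raise ValueError("arc segment is empty")
    if columns.shape != rows.shape:
        raise ValueError("columns and rows must have equal length")
    n_rows = int(image_shape[0])
    if not (0 <= bottom_offset < n_rows):
        raise ValueError(f"bottom_offset {bottom_offset} outside [0, {n_rows})")
    pts = np.column_stack([columns, rows])
    centroid = pts.mean(axis=0)
    copy = 2.0 * centroid - pts  # 180-degree rotation about the centroid
    target_bottom = (n_rows - 1) - bottom_offset
    copy[:, 1] += target_bottom - copy[:, 1].max()
    if copy[:, 1].min() < 0:
        raise ValueError("bottom_offset pushes the mirrored copy out of bounds")
    return np.vstack([pts, copy])


def _conic_uncenter(coef, mx, my):
    """Undo the centering x' = x - mx, y' = y - my of conic coefficients."""
    A, B, C, D, E, F = coef
    return (
        A,
        B,
        C,
        D - 2 * A * mx - B * my,
        E - 2 * C * my - B * mx,
        F + A * mx * mx + B * mx * my + C * my * my - D * mx - E * my,
    )


def _fit_ls_conic(x, y):
    # plain algebraic least squares: smallest singular vector of the design
    # matrix under a unit-norm constraint on all six coefficients
    Dm = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, _, Vt = np.linalg.svd(Dm, full_matrices=False)
    return Vt[-1]


def _fit_direct(x, y):
    # Fitzgibbon/Halir-Flusser direct fit with the ellipse-specific
    # constraint 4AC - B^2 = 1 (numerically stable block formulation)
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError:
        return None
    M = S1 + S2 @ T
    Cinv = np.array([[0, 0, 0.5], [0, -1.0, 0], [0.5, 0, 0]])
    M = Cinv @ M
    w, V = np.linalg.eig(M)
    # the admissible eigenvector satisfies 4ac - b^2 > 0
    cond = 4 * V[0] * V[2] - V[1] ** 2
    idx = np.flatnonzero(np.isreal(w) & (np.real(cond) > 0))
    if idx.size == 0:
        return None
    a1 = np.real(V[:, idx[0]])
    return np.concatenate([a1, T @ a1])


def _fit_taubin(x, y):
    # Taubin fit: gradient-weighted normalization, solved as a generalized
    # eigenproblem on centered moments
    Z = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    n = len(x)
    M = Z.T @ Z / n
    # gradient of the conic wrt (x, y): weight matrix
    P = np.zeros((6, 6))
    xm, ym = x.mean(), y.mean()
    x2m, y2m, xym = (x * x).mean(), (y * y).mean(), (x * y).mean()
    P[0, 0] = 4 * x2m
    P[0, 1] = P[1, 0] = 2 * xym
    P[0, 3] = P[3, 0] = 2 * xm
    P[1, 1] = x2m + y2m
    P[1, 3] = P[3, 1] = ym
    P[1, 4] = P[4, 1] = xm
    P[1, 2] = P[2, 1] = 2 * xym
    P[2, 2] = 4 * y2m
    P[2, 4] = P[4, 2] = 2 * ym
    P[3, 3] = 1.0
    P[4, 4] = 1.0
    try:
        from scipy.linalg import eig

        w, V = eig(M, P)
    except Exception:
        return None
    w = np.real_if_close(w)
    finite = np.isfinite(w) & (np.abs(np.imag(w)) < 1e-9)
    if not finite.any():
        return None
    idx = np.flatnonzero(finite)
    best = idx[np.argmin(np.abs(np.real(w[idx])))]
    return np.real(V[:, best])


_FITTERS = {"ls_conic": _fit_ls_conic, "direct": _fit_direct, "taubin": _fit_taubin}


def fit_ellipse(points: np.ndarray, method: str = "ls_conic") -> EllipseParams | None:
    """Fit an ellipse to 2-D points by algebraic least squares.

    Parameters
    ----------
    points : (N, 2) array of (x, y) coordinates, N >= 5.
    method : ``ls_conic`` (unit-norm conic LS, then classification),
        ``direct`` (ellipse-specific 4AC - B^2 = 1 constraint) or
        ``taubin`` (gradient-weighted normalization).

    Returns
    -------
    EllipseParams, or ``None`` when the best-fitting conic is not a real
    ellipse (degenerate/collinear input, parabola or hyperbola).  A ``None``
    result is the expected outcome for unmeasurable frames and is skipped,
    not raised, by batch drivers.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must have shape (N, 2)")
    if len(points) < 5:
        raise ValueError("ellipse fitting needs at least 5 points")
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_FITTERS)}")
    mx, my = points.mean(axis=0)
    x = points[:, 0] - mx
    y = points[:, 1] - my
    coef = _FITTERS[method](x, y)
    if coef is None or not np.all(np.isfinite(coef)):
        return None
    conic = _conic_uncenter(tuple(coef), mx, my)
    return ellipse_from_conic(conic)


def measure(ellipse: EllipseParams, image_shape: tuple[int, int]) -> Measurement:
    """Extract level and area in pixel units from a fitted ellipse.

    ``area_px2`` is pi times the product of the semi-axes.  ``level_px`` is
    the height, counted from the bottom image edge, of the horizontal line
    tangent to the top of the (possibly tilted) ellipse.
    """
    n_rows = int(image_shape[0])
    y_top = ellipse.center[1] - ellipse.vertical_half_extent()
    return Measurement(level_px=float(n_rows - y_top), area_px2=ellipse.area)
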