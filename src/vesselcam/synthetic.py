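"""Synthetic rim-camera scenes of the inside of a conical drinking glass.

A pinhole camera is mounted on the rim looking down into the glass; the
liquid surface is a horizontal circle whose radius follows the glass wall
profile.  Under the projection the circle maps to an exact conic (an
ellipse for every admissible fill), and the visible liquid-contact line is
the far-side (upper-image) branch of that ellipse.  The renderer draws the
contact line as a thin high-contrast curve over a radially shaded
background with a couple of specular blobs, and records the exact projected
ellipse and the drawn pixels as ground truth.

Images are float grids in [0, 1], 160 rows x 120 columns by default
(capture orientation of a portrait low-resolution camera frame), written to
disk as 8-bit grayscale PNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import imageio.v3 as iio
import numpy as np

from .ellipse import EllipseParams, Measurement, ellipse_from_conic, measure

__all__ = [
    "GlassSpec",
    "CameraSpec",
    "SceneTruth",
    "NoiseSpec",
    "table_glass",
    "render_scene",
    "add_noise",
    "write_scene",
    "DEFAULT_IMAGE_SHAPE",
]

DEFAULT_IMAGE_SHAPE = (160, 120)  # rows x cols


@dataclass(frozen=True)
class GlassSpec:
    """Conically shaped glass described by its wall-radius profile.

    ``radius_at(level_mm)`` returns the interior wall radius (mm) at a given
    liquid level above the base; ``reference_level_mm`` is the topmost
    calibrated level used as the fixed reference section for volume
    differencing.
    """

    radius_at: Callable[[float], float]
    height_mm: float
    reference_level_mm: float

    def __post_init__(self) -> None:
        if self.height_mm <= 0:
            raise ValueError("height_mm must be positive")
        if not 0 < self.reference_level_mm <= self.height_mm:
            raise ValueError("reference_level_mm must lie in (0, height_mm]")
        levels = np.linspace(0.0, self.height_mm, 25)
        if np.any(np.asarray([self.radius_at(l) for l in levels]) <= 0):
            raise ValueError("radius_at must be positive over [0, height_mm]")


def table_glass() -> GlassSpec:
    """The measured calibration glass: wall radius interpolated from the
    ground-truth (level, diameter) pairs of the bundled calibration table."""
    levels = np.array([0.0, 10, 20, 30, 40, 50, 60])
    radii = np.array([37.0, 36.5, 36.0, 35.5, 34.5, 33.5, 32.0])

    def radius_at(level_mm: float) -> float:
        return float(np.interp(level_mm, levels, radii))

    return GlassSpec(radius_at=radius_at, height_mm=60.0, reference_level_mm=60.0)


@dataclass(frozen=True)
class CameraSpec:
    """Pinhole camera clipped to the rim, looking down into the glass.

    The camera sits above the near rim point at ``mount_height_mm`` and
    points into the glass at ``declination_deg`` below the horizontal.
    ``focal_px`` is the focal length in pixel units.
    """

    declination_deg: float = 40.0
    focal_px: float = 110.0
    mount_height_mm: float = 15.0


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth recorded while rendering a scene."""

    level_mm: float
    arc_points: np.ndarray  # (N, 2) integer (row, col) pixels actually drawn
    ellipse_truth: EllipseParams | None
    image_shape: tuple[int, int]

    @property
    def tangent_row(self) -> float | None:
        """Topmost (minimum) row of the drawn arc; None for an empty glass."""
        if len(self.arc_points) == 0:
            return None
        return float(self.arc_points[:, 0].min())

    def truth_measurement(self) -> Measurement | None:
        if self.ellipse_truth is None:
            return None
        return measure(self.ellipse_truth, self.image_shape)


@dataclass(frozen=True)
class NoiseSpec:
    """Controlled degradation: Gaussian intensity noise plus salt & pepper."""

    gaussian_variance: float = 0.0
    sp_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_variance < 0:
            raise ValueError("gaussian_variance must be >= 0")
        if not 0.0 <= self.sp_density <= 1.0:
            raise ValueError("sp_density must lie in [0, 1]")


def _camera_frame(glass: GlassSpec, cam: CameraSpec, image_shape):
    rows, cols = image_shape
    d = np.deg2rad(cam.declination_deg)
    position = np.array([0.0, -glass.radius_at(glass.height_mm),
                         glass.height_mm + cam.mount_height_mm])
    forward = np.array([0.0, np.cos(d), -np.sin(d)])
    right = np.array([1.0, 0.0, 0.0])
    down = np.cross(forward, right)
    R = np.vstack([right, down, forward])
    K = np.array([[cam.focal_px, 0.0, (cols - 1) / 2.0],
                  [0.0, cam.focal_px, (rows - 1) / 2.0],
                  [0.0, 0.0, 1.0]])
    return K, R, position


def _projected_conic(glass: GlassSpec, level_mm: float, cam: CameraSpec,
                     image_shape) -> EllipseParams | None:
    """Exact image conic of the liquid circle at ``level_mm``.

    The liquid plane z = level maps to the image by the homography
    H = K [r1 r2 R(p - C)]; the circle's conic Q = diag(1, 1, -r^2)
    transforms as H^-T Q H^-1.
    """
    K, R, C = _camera_frame(glass, cam, image_shape)
    r = glass.radius_at(level_mm)
    t = R @ (np.array([0.0, 0.0, level_mm]) - C)
    H = K @ np.column_stack([R[:, 0], R[:, 1], t])
    Hi = np.linalg.inv(H)
    Q = np.diag([1.0, 1.0, -r * r])
    Cm = Hi.T @ Q @ Hi
    Cm /= np.linalg.norm(Cm)
    # sign convention: interior of the ellipse negative
    A, B, Cc = Cm[0, 0], 2 * Cm[0, 1], Cm[1, 1]
    D, E, F = 2 * Cm[0, 2], 2 * Cm[1, 2], Cm[2, 2]
    return ellipse_from_conic((A, B, Cc, D, E, F))


def _upper_branch(params: EllipseParams, cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Float row of the upper (far-side) ellipse branch for each integer
    column inside the ellipse's horizontal span, before image clipping."""
    A, B, C, D, E, F = params.conic
    x = np.arange(cols, dtype=float)
    # C y^2 + (B x + E) y + (A x^2 + D x + F) = 0
    b = B * x + E
    c = A * x * x + D * x + F
    disc = b * b - 4 * C * c
    ok = disc > 0
    y_upper = np.full(cols, np.nan)
    y_upper[ok] = (-b[ok] - np.sqrt(disc[ok])) / (2 * C) if C > 0 else \
        (-b[ok] + np.sqrt(disc[ok])) / (2 * C)
    # choose the smaller root (smaller row = upper branch)
    y_other = np.full(cols, np.nan)
    y_other[ok] = (-b[ok] + np.sqrt(disc[ok])) / (2 * C) if C > 0 else \
        (-b[ok] - np.sqrt(disc[ok])) / (2 * C)
    y = np.fmin(y_upper, y_other)
    return x[ok], y[ok]


def render_scene(glass: GlassSpec, fill_level_mm: float,
                 image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
                 camera: CameraSpec = CameraSpec(),
                 seed: int = 0,
                 arc_intensity: float = 0.95,
                 n_specular: int = 2) -> tuple[np.ndarray, SceneTruth]:
    """Render a rim-camera view of the glass interior at a given fill.

    Returns the float image in [0, 1] and the :class:`SceneTruth` recording
    the exact projected ellipse and the drawn arc pixels.  ``fill_level_mm``
    of zero renders an empty glass: background only, no arc, no ellipse.
    """
    rows, cols = int(image_shape[0]), int(image_shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("image_shape must be positive")
    if not 0.0 <= fill_level_mm <= glass.height_mm:
        raise ValueError(
            f"fill level {fill_level_mm} mm outside glass range [0, {glass.height_mm}]")
    rng = np.random.default_rng(seed)

    # radially shaded background: a gentle vignette toward the borders,
    # shallow enough that its gradient stays below the documented edge
    # threshold and the contact line is the dominant gradient
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    rnorm = np.hypot((rr - (rows - 1) / 2) / rows, (cc - (cols - 1) / 2) / cols)
    image = 0.42 - 0.08 * rnorm**2 / rnorm.max() ** 2

    # specular clutter: small bright Gaussian blobs at seeded positions
    for _ in range(n_specular):
        br = rng.uniform(0.15 * rows, 0.85 * rows)
        bc = rng.uniform(0.15 * cols, 0.85 * cols)
        amp = rng.uniform(0.25, 0.4)
        sigma = rng.uniform(2.0, 4.0)
        image += amp * np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2 * sigma**2))

    arc_pixels: list[tuple[int, int]] = []
    ellipse_truth: EllipseParams | None = None
    if fill_level_mm > 0:
        ellipse_truth = _projected_conic(glass, fill_level_mm, camera, (rows, cols))
        if ellipse_truth is None:  # pragma: no cover - admissible geometry only
            raise RuntimeError("camera geometry projected a non-elliptical conic")
        xs, ys = _upper_branch(ellipse_truth, cols)
        for x, y in zip(xs, ys):
            r0 = int(np.floor(y))
            for r_px in (r0, r0 + 1):  # 2-px-wide contact line
                if 0 <= r_px < rows:
                    image[r_px, int(x)] = arc_intensity
                    arc_pixels.append((r_px, int(x)))

    image = np.clip(image, 0.0, 1.0)
    truth = SceneTruth(
        level_mm=float(fill_level_mm),
        arc_points=np.array(arc_pixels, dtype=int).reshape(-1, 2),
        ellipse_truth=ellipse_truth,
        image_shape=(rows, cols),
    )
    return image, truth


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Degrade an image with Gaussian noise then salt & pepper speckle.

    With density d each pixel is independently replaced by 0 or 1 (equal
    probability) with probability d.  Reproducible for a fixed seed; a
    zero-noise spec returns the input unchanged (same buffer contents).
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    if spec.gaussian_variance == 0 and spec.sp_density == 0:
        return image.copy()
    rng = np.random.default_rng(spec.seed)
    out = image.copy()
    if spec.gaussian_variance > 0:
        out = out + rng.normal(0.0, np.sqrt(spec.gaussian_variance), size=out.shape)
        out = np.clip(out, 0.0, 1.0)
    if spec.sp_density > 0:
        hit = rng.random(out.shape) < spec.sp_density
        salt = rng.random(out.shape) < 0.5
        out[hit & salt] = 1.0
        out[hit & ~salt] = 0.0
    return out


def write_scene(image: np.ndarray, truth: SceneTruth, stem: Path | str) -> tuple[Path, Path]:
    """Write the image as 8-bit grayscale PNG plus a JSON truth sidecar."""
    stem = Path(stem)
    png_path = stem.with_suffix(".png")
    json_path = stem.with_suffix(".json")
    iio.imwrite(png_path, np.round(image * 255).astype(np.uint8))
    payload = {
        "level_mm": truth.level_mm,
        "image_shape": list(truth.image_shape),
        "arc_points": truth.arc_points.tolist(),
        "ellipse_truth": None
        if truth.ellipse_truth is None
        else {
            "conic": list(truth.ellipse_truth.conic),
            "center": list(truth.ellipse_truth.center),
            "semi_major": truth.ellipse_truth.semi_major,
            "semi_minor": truth.ellipse_truth.semi_minor,
            "tilt": truth.ellipse_truth.tilt,
        },
    }
    json_path.write_text(json.dumps(payload))
    return png_path, json_path
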