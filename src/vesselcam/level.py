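"""Curve-scan detection of the liquid-level arc in a binary mask.

The liquid-contact line has an approximately quadratic image profile
``row = a*col^2 + b*col + c``.  A family of such curves — fixed curvature
``a``, a handful of slope values ``b``, intercept ``c`` swept over every
row — is rasterized over the labelled mask, and the connected component
intersected by the single best-scoring curve is taken to be the level
segment.  The component is then pruned of vertically thick clutter,
collapsed to one row per column, bridged across gaps and smoothed.

An empty mask (or a component that prunes away entirely) is a valid
"no level detected" outcome — an empty glass shows no contact line — and is
signalled by ``None`` rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

__all__ = ["ScanParams", "ScanHit", "ArcSegment", "scan_curves", "extract_level_segment"]


@dataclass(frozen=True)
class ScanParams:
    """Quadratic scan-curve family ``row = a*col^2 + b*col + c``.

    Defaults follow the measurement procedure for 160x120 frames: curvature
    0.003 row/col^2 and four slope steps spanning the observed line-of-
    symmetry range b in [-0.58, -0.14]; c visits every row index.
    """

    a: float = 0.003
    b_min: float = -0.58
    b_max: float = -0.14
    b_steps: int = 4

    def __post_init__(self) -> None:
        if self.b_steps < 1:
            raise ValueError("b_steps must be >= 1")
        if self.b_min > self.b_max:
            raise ValueError("b_min must be <= b_max")

    def b_values(self) -> np.ndarray:
        if self.b_steps == 1:
            return np.array([0.5 * (self.b_min + self.b_max)])
        return np.linspace(self.b_min, self.b_max, self.b_steps)


@dataclass(frozen=True)
class ScanHit:
    """Winning component of the curve scan."""

    component_id: int
    overlap: int  # pixels of the component hit by the best single curve
    b: float
    c: int


@dataclass(frozen=True)
class ArcSegment:
    """One-row-per-column trace of the detected liquid-level arc."""

    columns: np.ndarray  # contiguous integer columns
    rows: np.ndarray  # float representative row per column
    component_id: int
    overlap: int

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.rows):
            raise ValueError("columns and rows must have equal length")
        if len(self.columns) and np.any(np.diff(self.columns) != 1):
            raise ValueError("columns must be contiguous")

    @property
    def mean_row(self) -> float:
        return float(np.mean(self.rows))


def rasterize_curve(a: float, b: float, c: float, cols: int) -> np.ndarray:
    """Integer row per column of the quadratic curve (no anti-aliasing)."""
    x = np.arange(cols, dtype=float)
    return np.rint(a * x * x + b * x + c).astype(int)


def scan_curves(mask: np.ndarray, params: ScanParams = ScanParams(),
                labels: np.ndarray | None = None) -> ScanHit | None:
    """Exhaustively scan the quadratic curve family over the labelled mask.

    For every intercept ``c`` (each row index) and each of the ``b_steps``
    slope values, the curve is rasterized and the number of its pixels
    landing on each connected component is counted.  The component with the
    maximum single-curve overlap wins; ties break toward the smallest
    ``c`` then the smallest ``b``.

    Returns ``None`` when the mask is empty ("no level detected").
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D binary mask")
    if not mask.any():
        return None
    if labels is None:
        labels = skmeasure.label(mask, connectivity=2)
    n_rows, n_cols = mask.shape
    n_labels = int(labels.max())
    x = np.arange(n_cols)

    best: tuple[int, int, float, int] | None = None  # (overlap, comp, b, c)
    for b in params.b_values():
        base = np.rint(params.a * x * x.astype(float) + b * x).astype(int)
        for c in range(n_rows):
            rows = base + c
            ok = (rows >= 0) & (rows < n_rows)
            if not ok.any():
                continue
            hit_labels = labels[rows[ok], x[ok]]
            hit_labels = hit_labels[hit_labels > 0]
            if hit_labels.size == 0:
                continue
            counts = np.bincount(hit_labels, minlength=n_labels + 1)
            comp = int(counts.argmax())
            overlap = int(counts[comp])
            # tie-breaking: larger overlap wins; then smaller c, then smaller b
            if (best is None or overlap > best[0]
                    or (overlap == best[0] and (c, b) < (best[3], best[2]))):
                best = (overlap, comp, float(b), int(c))
    if best is None:  # pragma: no cover - nonempty masks always intersect
        return None
    overlap, comp, b, c = best
    return ScanHit(component_id=comp, overlap=overlap, b=b, c=c)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(values) < 2:
        return values.astype(float)
    window = min(int(window), len(values))
    if window % 2 == 0:
        window -= 1
    if window <= 1:
        return values.astype(float)
    half = window // 2
    padded = np.pad(values.astype(float), half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def extract_level_segment(mask: np.ndarray, component_id: int,
                          prune_width: int | None = None, smooth_window: int = 5,
                          labels: np.ndarray | None = None,
                          guide: tuple[float, float, float] | None = None) -> ArcSegment | None:
    """Reduce the winning component to a clean one-row-per-column trace.

    Per column, vertical runs of the component taller than ``prune_width``
    are dropped (they are clutter attached to the thin arc); surviving
    pixels collapse to their vertical centroid.  Missing interior columns
    are bridged by linear interpolation so the trace covers the full column
    span, and the result is smoothed by a centered moving average.

    ``prune_width=None`` (the default) adapts the cut to the component:
    runs taller than 1.5x the median column height are dropped.  A gradient
    mask of a thin bright curve is a band several pixels tall (the edge
    responds on both sides of the ridge), so an absolute width cannot
    separate arc from clutter across blur settings, while attached blobs
    are reliably much taller than the band's typical height.

    When a column still holds several surviving runs, ``guide`` — the
    winning scan curve's ``(a, b, c)`` — selects the run nearest the
    predicted curve row; without a guide all surviving pixels are averaged.

    Returns ``None`` if pruning removes every column.
    """
    mask = np.asarray(mask, dtype=bool)
    if labels is None:
        labels = skmeasure.label(mask, connectivity=2)
    comp = labels == component_id
    if not comp.any():
        raise ValueError(f"component {component_id} not present in mask")
    if prune_width is None:
        heights = comp.sum(axis=0)
        prune_width = max(3, int(np.ceil(1.5 * np.median(heights[heights > 0]))))
    if prune_width < 1:
        raise ValueError("prune_width must be >= 1")

    n_rows, n_cols = comp.shape
    col_rows: dict[int, float] = {}
    for col in range(n_cols):
        rows = np.flatnonzero(comp[:, col])
        if rows.size == 0:
            continue
        # split into vertical runs, keep runs of height <= prune_width
        breaks = np.flatnonzero(np.diff(rows) > 1)
        runs = [r for r in np.split(rows, breaks + 1) if len(r) <= prune_width]
        if not runs:
            continue
        if len(runs) > 1 and guide is not None:
            ga, gb, gc = guide
            predicted = ga * col * col + gb * col + gc
            runs = [min(runs, key=lambda r: abs(float(r.mean()) - predicted))]
        kept = np.concatenate(runs)
        col_rows[col] = float(kept.mean())
    if not col_rows:
        return None

    cols_known = np.array(sorted(col_rows))
    rows_known = np.array([col_rows[c] for c in cols_known])
    span = np.arange(cols_known[0], cols_known[-1] + 1)
    trace = np.interp(span, cols_known, rows_known)
    trace = _moving_average(trace, smooth_window)
    overlap = int(comp.sum())
    return ArcSegment(columns=span, rows=trace, component_id=int(component_id),
                      overlap=overlap)
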