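"""End-to-end wiring: simulate -> segment -> detect -> fit -> calibrate ->
volume -> agreement, with a validated configuration and file artifacts."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import agreement as agreement_mod
from . import calibration as calib_mod
from . import segmentation as seg
from .ellipse import Measurement, fit_ellipse, measure, mirror_segment
from .level import ScanParams, extract_level_segment, scan_curves
from .synthetic import (
    DEFAULT_IMAGE_SHAPE,
    CameraSpec,
    GlassSpec,
    NoiseSpec,
    add_noise,
    render_scene,
    table_glass,
    write_scene,
)
from .volume import frustum_volume, ground_truth_volume, inferred_volume

logger = logging.getLogger("vesselcam")

__all__ = ["PipelineConfig", "measure_image", "run_measure", "run_end_to_end",
           "load_image", "load_config"]


class SegmentationConfig(BaseModel):
    edge: Literal["sobel", "canny", "vesselness"] = "sobel"
    disk_radius: int = Field(3, ge=1)
    sobel_threshold: float | Literal["auto"] = 0.005
    vesselness_scales: tuple[float, ...] = (1.0, 2.0, 3.0)
    line_length: int = Field(3, ge=1)


class ScanConfig(BaseModel):
    a: float = 0.003
    b_min: float = -0.58
    b_max: float = -0.14
    b_steps: int = Field(4, ge=1)
    prune_width: int | None = Field(None, ge=1)  # None = adaptive (2x median height)
    smooth_window: int = Field(5, ge=1)

    @model_validator(mode="after")
    def _check_range(self):
        if self.b_min > self.b_max:
            raise ValueError("scan.b_min must be <= scan.b_max")
        return self


class SimulateConfig(BaseModel):
    levels_mm: tuple[float, ...] = (10, 20, 30, 40, 50, 60)
    replicates: int = Field(3, ge=1)
    gaussian_variance: float = Field(0.0, ge=0)
    sp_density: float = Field(0.0, ge=0, le=1)


class PipelineConfig(BaseModel):
    """Validated configuration shared by every pipeline stage."""

    seed: int = 0
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE
    segmentation: SegmentationConfig = SegmentationConfig()
    scan: ScanConfig = ScanConfig()
    mirror_bottom_offset: float = Field(50.0, ge=0)
    fit_method: Literal["ls_conic", "direct", "taubin"] = "ls_conic"
    fit_gate_px: float = Field(3.0, gt=0)  # max central trace-to-ellipse RMS
    min_span_frac: float = Field(0.3, gt=0, le=1)  # min arc width / image width
    outlier_k: float = Field(2.5, gt=0)
    volume_convention: Literal["table", "between_levels"] = "table"
    simulate: SimulateConfig = SimulateConfig()

    def scan_params(self) -> ScanParams:
        return ScanParams(a=self.scan.a, b_min=self.scan.b_min,
                          b_max=self.scan.b_max, b_steps=self.scan.b_steps)


def load_config(path: Path | str | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)


def load_image(path: Path | str) -> np.ndarray:
    """Read a PNG/JPEG as a float grayscale grid in [0, 1]."""
    arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def _build_mask(image: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    s = cfg.segmentation
    if s.edge == "sobel":
        mask = seg.sobel_mask(seg.preblur(image, s.disk_radius), s.sobel_threshold)
    elif s.edge == "canny":
        mask = seg.canny_mask(seg.preblur(image, s.disk_radius))
    else:
        mask = seg.vesselness_mask(image, s.vesselness_scales)
    return seg.refine_mask(mask, s.line_length)


def _central_fit_deviation(ellipse, segment) -> float:
    """RMS row distance between the fitted ellipse's upper branch and the
    central third of the extracted trace (the region the level is read
    from).  Large values mean the mirror reconstruction degenerated and the
    fit no longer follows the detected arc."""
    A, B, C, D, E, F = ellipse.conic
    x = segment.columns.astype(float)
    bq = B * x + E
    cq = A * x * x + D * x + F
    disc = bq * bq - 4 * C * cq
    if C == 0:
        return np.inf
    root = np.sqrt(np.maximum(disc, 0.0))
    y_upper = np.minimum((-bq - root) / (2 * C), (-bq + root) / (2 * C))
    n = len(x)
    sel = slice(n // 3, max(n // 3 + 1, 2 * n // 3))
    ok = disc[sel] > 0
    if not ok.any():
        return np.inf
    dev = y_upper[sel][ok] - segment.rows[sel][ok]
    return float(np.sqrt(np.mean(dev**2)))


def measure_image(image: np.ndarray, cfg: PipelineConfig | None = None) -> Measurement | None:
    """Full single-frame measurement; ``None`` when no level is detected,
    no ellipse can be fitted, or the fitted ellipse fails the
    reconstruction-quality gate (an empty or unmeasurable frame)."""
    cfg = cfg or PipelineConfig()
    mask = _build_mask(image, cfg)
    hit = scan_curves(mask, cfg.scan_params())
    if hit is None:
        return None
    segment = extract_level_segment(mask, hit.component_id,
                                    prune_width=cfg.scan.prune_width,
                                    smooth_window=cfg.scan.smooth_window,
                                    guide=(cfg.scan.a, hit.b, hit.c))
    if segment is None:
        return None
    if len(segment.columns) < cfg.min_span_frac * image.shape[1]:
        # the contact line spans most of the frame width by geometry; a
        # narrow trace is clutter (specular blob, rim fragment), not a level
        return None
    points = mirror_segment(segment.columns, segment.rows,
                            cfg.mirror_bottom_offset, image.shape)
    ellipse = fit_ellipse(points, method=cfg.fit_method)
    if ellipse is None:
        return None
    if _central_fit_deviation(ellipse, segment) > cfg.fit_gate_px:
        return None
    return measure(ellipse, image.shape)


def run_measure(images: Sequence[Path | str] | Sequence[np.ndarray],
                cfg: PipelineConfig | None = None,
                ids: Sequence | None = None) -> pd.DataFrame:
    """Measure a batch of frames into a tidy table.

    Unreadable or unmeasurable frames are recorded with status != "ok" and
    missing pixel columns, so batch summaries can skip them the way the
    calibration table skips its failed frame.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for i, item in enumerate(images):
        ident = ids[i] if ids is not None else i
        t0 = time.perf_counter()
        status = "ok"
        level_px = area_px2 = np.nan
        try:
            image = item if isinstance(item, np.ndarray) else load_image(item)
            m = measure_image(image, cfg)
            if m is None:
                status = "no_level"
            else:
                level_px, area_px2 = m.level_px, m.area_px2
        except Exception as exc:  # unreadable/corrupt frames must not abort the batch
            logger.warning("frame %s failed: %s", ident, exc)
            status = "failed"
        rows.append({"image": ident, "level_px": level_px, "area_px2": area_px2,
                     "status": status, "elapsed_s": time.perf_counter() - t0})
    return pd.DataFrame(rows)


def run_end_to_end(cfg: PipelineConfig | None = None,
                   glass: GlassSpec | None = None,
                   camera: CameraSpec = CameraSpec(),
                   outdir: Path | str | None = None,
                   plot: bool = False) -> dict:
    """Simulate a fill sweep, measure it, self-calibrate, and score agreement.

    The synthetic sweep plays the role of the captured dataset: scenes are
    rendered at the configured levels, pushed through the measurement
    pipeline, the two calibration maps are fitted against the generator's
    ground truth, and inferred volumes are compared with ground-truth
    frustum volumes in a Bland-Altman report.  All artifacts are derived
    from (config, seed) alone, so reruns are bit-identical.
    """
    cfg = cfg or PipelineConfig()
    glass = glass or table_glass()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    sim = cfg.simulate
    records = []
    for level in sim.levels_mm:
        for rep in range(sim.replicates):
            scene_seed = cfg.seed * 100003 + int(round(level * 16)) * 131 + rep
            scene_seed %= 2**31
            t0 = time.perf_counter()
            image, truth = render_scene(glass, level, cfg.image_shape,
                                        camera=camera, seed=scene_seed)
            if sim.gaussian_variance > 0 or sim.sp_density > 0:
                image = add_noise(image, NoiseSpec(sim.gaussian_variance,
                                                   sim.sp_density, scene_seed + 1))
            if out is not None:
                write_scene(image, truth, out / f"scene_L{level:05.1f}_r{rep}")
            m = measure_image(image, cfg)
            logger.info("simulate+measure level=%.1f rep=%d: %.3fs",
                        level, rep, time.perf_counter() - t0)
            records.append({
                "level_mm": level,
                "replicate": rep,
                "radius_mm": glass.radius_at(level),
                "level_px": np.nan if m is None else m.level_px,
                "area_px2": np.nan if m is None else m.area_px2,
                "status": "ok" if m is not None else "no_level",
            })
    frames = pd.DataFrame(records)
    if int(frames["level_px"].notna().sum()) < 6:
        raise RuntimeError("too few measurable synthetic frames to calibrate")

    # screen gross measurement failures before fitting, as the published
    # calibration did (its low-fill frames were the flagged rows)
    screen = frames.assign(diameter_mm=2.0 * frames["radius_mm"])
    flags = calib_mod.flag_outliers(screen, k=cfg.outlier_k)
    frames["outlier"] = flags
    ok = frames.loc[~flags].dropna(subset=["level_px", "area_px2"])
    if len(ok) < 5:
        raise RuntimeError("too few usable synthetic frames to calibrate")

    level_model, level_stats = calib_mod.fit_level_model(
        ok["level_px"], ok["level_mm"])
    area_model, area_stats = calib_mod.fit_area_model(
        ok["area_px2"], np.pi * ok["radius_mm"] ** 2)

    ref = (glass.reference_level_mm, glass.radius_at(glass.reference_level_mm))
    truth_vol, est_vol = [], []
    for _, row in ok.iterrows():
        truth_vol.append(ground_truth_volume(row["level_mm"], row["radius_mm"],
                                             ref, cfg.volume_convention).volume_ml)
        m = Measurement(level_px=row["level_px"], area_px2=row["area_px2"])
        est_vol.append(inferred_volume(m, level_model, area_model, ref,
                                       cfg.volume_convention).volume_ml)
    report = agreement_mod.bland_altman(truth_vol, est_vol)

    result = {
        "frames": frames,
        "level_model": level_model,
        "level_stats": level_stats,
        "area_model": area_model,
        "area_stats": area_stats,
        "reference": ref,
        "volumes": pd.DataFrame({"level_mm": ok["level_mm"].to_numpy(),
                                 "truth_ml": truth_vol, "inferred_ml": est_vol}),
        "agreement": report,
    }
    if out is not None:
        frames.to_csv(out / "measurements.csv", index=False)
        result["volumes"].to_csv(out / "volumes.csv", index=False)
        payload = {
            "level_model": level_model.__dict__,
            "level_stats": level_stats.__dict__,
            "area_model": area_model.__dict__,
            "area_stats": area_stats.__dict__,
            "agreement": report.as_dict(),
            "reference": {"level_mm": ref[0], "radius_mm": ref[1]},
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        if plot:
            agreement_mod.plot_bland_altman(report, truth_vol, est_vol,
                                            out / "bland_altman.png")
    return result
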