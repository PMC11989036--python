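"""Pipeline orchestration: detect -> consolidate -> quantify on a slide,
dataset generation, and batch evaluation.

The functions here are what the CLI wraps; they are importable directly
for scripted use.  A :class:`PipelineConfig` collects every knob with
its default; defaults that the user did not override are logged, since
several of them (NMS threshold, confidence cutoff, tile overlap) have
no published reference value and materially affect counts.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw

from . import imgio, quantify, tiling
from .detect import DetectorParams, get_detector
from .errors import ValidationError
from .evaluate import EvalReport, evaluate_batch
from .geometry import OrientedBox
from .imgio import RasterImage

__all__ = ["PipelineConfig", "load_config", "run_quantify", "run_quantify_batch",
           "run_generate", "run_evaluate", "draw_overlay"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    tile_size: int = 1024
    overlap: int = 128
    dedup_iou: float = 0.5
    conf_thresh: float = 0.25
    detector: str = "classical"
    detector_params: DetectorParams = field(default_factory=DetectorParams)
    sat_thresh: float = 0.08
    close_radius_px: int = 5
    open_radius_px: int = 3
    min_object_px: int = 10_000
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.tile_size):
            raise ValidationError("need 0 <= overlap < tile_size")
        if not (0.0 < self.dedup_iou <= 1.0):
            raise ValidationError("dedup_iou must lie in (0, 1]")
        if not (0.0 <= self.conf_thresh <= 1.0):
            raise ValidationError("conf_thresh must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector_params"] = dataclasses.asdict(self.detector_params)
        return d


_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"detector_params"}
_DETECTOR_KEYS = {f.name for f in dataclasses.fields(DetectorParams)}
_INT_KEYS = {"tile_size", "overlap", "close_radius_px", "open_radius_px",
             "min_object_px", "min_area_px", "max_area_px", "open_radius_px"}


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Build a config from a ``key = value`` text file plus overrides.

    Detector parameters use their own names (``dab_od_thresh`` etc.) in
    the same flat namespace.  CLI overrides take precedence over the
    file; unset keys keep their defaults and are logged.
    """
    raw: Dict[str, str] = {}
    if path:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(f"{path}:{lineno}: expected key = value")
                k, v = (s.strip() for s in line.split("=", 1))
                raw[k] = v
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    cfg_kwargs: Dict[str, object] = {}
    det_kwargs: Dict[str, object] = {}
    for k, v in raw.items():
        if k in _DETECTOR_KEYS:
            det_kwargs[k] = int(v) if k in _INT_KEYS else float(v)
        elif k in _CONFIG_KEYS:
            if k == "detector":
                cfg_kwargs[k] = str(v)
            elif k in _INT_KEYS:
                cfg_kwargs[k] = int(v)
            else:
                cfg_kwargs[k] = float(v)
        else:
            raise ValidationError(f"unknown config key {k!r}")
    if det_kwargs:
        cfg_kwargs["detector_params"] = DetectorParams(**det_kwargs)
    cfg = PipelineConfig(**cfg_kwargs)
    for name in sorted(_CONFIG_KEYS - set(cfg_kwargs)):
        log.info("config: %s not set, using default %r", name, getattr(cfg, name))
    return cfg


def _detect_slide(image: RasterImage, config: PipelineConfig) -> List[OrientedBox]:
    """Tile the slide, run the detector per tile, consolidate globally."""
    detector = get_detector(config.detector, params=config.detector_params) \
        if config.detector == "classical" else get_detector(config.detector)
    grid = tiling.plan_tiles(image.width, image.height,
                             config.tile_size, config.overlap)
    per_tile = []
    for idx, tile in enumerate(tiling.extract_tiles(image, grid)):
        per_tile.append(tiling.TileDetections(idx, detector.detect(tile)))
    return tiling.consolidate(per_tile, grid, config.dedup_iou)


def draw_overlay(image: RasterImage, boxes: Sequence[OrientedBox],
                 mask: Optional[np.ndarray], path: str) -> None:
    """PNG overlay: detection boxes in red, tissue boundary in green."""
    im = Image.fromarray(np.asarray(image.pixels, dtype=np.uint8)).convert("RGB")
    if mask is not None:
        from skimage.segmentation import find_boundaries
        boundary = find_boundaries(mask, mode="outer")
        arr = np.array(im)
        arr[boundary] = (0, 200, 0)
        im = Image.fromarray(arr)
    draw = ImageDraw.Draw(im)
    for b in boxes:
        pts = [tuple(p) for p in b.corners()]
        draw.polygon(pts, outline=(220, 30, 30))
    im.save(path)


def run_quantify(
    slide_path: str,
    config: PipelineConfig,
    out_dir: Optional[str] = None,
) -> quantify.DensityReport:
    """Full single-slide pipeline: tissue mask, detection, density.

    With ``out_dir`` set, writes ``<stem>.overlay.png``,
    ``<stem>.report.json`` and ``<stem>.report.csv``.
    """
    image = imgio.read_image(slide_path, pixel_size_override=config.pixel_size_um)
    tmask = quantify.tissue_mask(
        image, sat_thresh=config.sat_thresh,
        close_radius_px=config.close_radius_px,
        open_radius_px=config.open_radius_px,
        min_object_px=config.min_object_px)
    boxes = _detect_slide(image, config)
    kept = [b for b in boxes if b.score >= config.conf_thresh]
    if tmask.n_pixels > 0:
        area = quantify.area_mm2(tmask, image.pixel_size_um)
    else:
        area = 0.0
    dens = quantify.density(len(kept), area) if (area > 0 or not kept) else None
    report = quantify.DensityReport(
        n_cells=len(kept), tissue_area_mm2=area, density_per_mm2=dens,
        conf_thresh_used=config.conf_thresh,
        slide=os.path.basename(slide_path))
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        stem = os.path.splitext(os.path.basename(slide_path))[0]
        draw_overlay(image, kept, tmask.mask,
                     os.path.join(out_dir, stem + ".overlay.png"))
        payload = report.to_dict()
        payload["config"] = config.to_dict()
        imgio.write_report(payload,
                           json_path=os.path.join(out_dir, stem + ".report.json"),
                           csv_path=os.path.join(out_dir, stem + ".report.csv"))
    return report


def run_quantify_batch(
    slide_paths: Sequence[str],
    config: PipelineConfig,
    out_dir: Optional[str] = None,
) -> List[quantify.DensityReport]:
    """Quantify several slides; attaches a 95% t-CI for the mean density
    when at least two slides have a defined density."""
    reports = [run_quantify(p, config, out_dir=out_dir) for p in slide_paths]
    densities = [r.density_per_mm2 for r in reports if r.density_per_mm2 is not None]
    if len(densities) >= 2:
        ci = quantify.mean_density_ci(densities, level=0.95)
        for r in reports:
            r.mean_density_ci = ci
    if out_dir:
        imgio.write_report(reports,
                           json_path=os.path.join(out_dir, "batch.report.json"),
                           csv_path=os.path.join(out_dir, "batch.report.csv"))
    return reports


def run_generate(spec_kwargs: dict, n_images: int, val_fraction: float,
                 out_dir: str) -> dict:
    """Generate a synthetic train/val dataset (thin wrapper)."""
    from .synthdata import SynthSpec, make_dataset
    return make_dataset(SynthSpec(**spec_kwargs), n_images, val_fraction, out_dir)


def run_evaluate(
    pred_dir: str,
    label_dir: str,
    img_dir: Optional[str] = None,
    conf_thresh: float = 0.25,
    mode: str = "pooled",
    default_size: Tuple[int, int] = (1024, 1024),
) -> EvalReport:
    """Evaluate prediction label files against ground-truth label files.

    Files are paired by stem; unpaired files are warned about and
    skipped.  Corner de-normalisation needs image dimensions, taken from
    a same-stem image in ``img_dir`` when given, else ``default_size``.
    """
    def _stems(d: str) -> Dict[str, str]:
        return {os.path.splitext(f)[0]: os.path.join(d, f)
                for f in sorted(os.listdir(d)) if f.endswith(".txt")}

    preds_by_stem = _stems(pred_dir)
    gts_by_stem = _stems(label_dir)
    common = sorted(set(preds_by_stem) & set(gts_by_stem))
    for stem in sorted(set(preds_by_stem) ^ set(gts_by_stem)):
        log.warning("evaluate: unpaired label stem %r skipped", stem)
    if not common:
        raise ValidationError("no prediction/label pairs found")

    images: Dict[str, str] = {}
    if img_dir:
        for f in sorted(os.listdir(img_dir)):
            stem, ext = os.path.splitext(f)
            if ext.lower() in (".tif", ".tiff", ".png", ".jpg", ".jpeg"):
                images.setdefault(stem, os.path.join(img_dir, f))

    pairs = []
    for stem in common:
        if stem in images:
            img = imgio.read_image(images[stem])
            w, h = img.width, img.height
        else:
            w, h = default_size
        pairs.append((imgio.read_labels(preds_by_stem[stem], w, h),
                      imgio.read_labels(gts_by_stem[stem], w, h)))
    return evaluate_batch(pairs, conf_thresh=conf_thresh, mode=mode)
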