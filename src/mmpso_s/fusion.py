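"""Map fusion and morphological post-processing, plus the full pipeline.

The two segmentation routes run in parallel — the swarm-thresholded dark
map ``I1`` and the refined superpixel map ``Ithresh`` — and are merged by
pixelwise union into ``Imerge``, which adds whole-cluster support around
the thresholded regions and smooths their borders.  Post-processing then
fills enclosed holes, smooths edges by morphological opening-then-closing
with a disk, and removes connected components below a minimum area
(8-connectivity throughout), yielding the final mask ``Ioutput``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .exceptions import ConfigError, InvalidInputError, PipelineError
from .imageprep import preprocess
from .mopso import SwarmConfig, apply_thresholds, run_mmpso
from .superpixel import SuperpixelConfig, refine_clusters, run_superpixel

__all__ = ["PostprocessConfig", "merge_maps", "postprocess", "run_pipeline"]

# 8-connectivity structuring element for hole filling / component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PostprocessConfig:
    """min_roi_area in pixels, smooth_radius in pixels (disk), and whether
    to fill background-enclosed holes."""

    min_roi_area: int = 30
    smooth_radius: int = 2
    fill_holes: bool = True

    def validate(self) -> "PostprocessConfig":
        if self.min_roi_area < 0:
            raise ConfigError(f"min_roi_area must be >= 0, got {self.min_roi_area}")
        if self.smooth_radius < 0:
            raise ConfigError(f"smooth_radius must be >= 0, got {self.smooth_radius}")
        return self


def merge_maps(i1: np.ndarray, ithresh: np.ndarray) -> np.ndarray:
    """Pixelwise union of the two segmentation maps."""
    i1 = np.asarray(i1, dtype=bool)
    ithresh = np.asarray(ithresh, dtype=bool)
    if i1.shape != ithresh.shape:
        raise InvalidInputError(f"mask shapes differ: {i1.shape} vs {ithresh.shape}")
    return i1 | ithresh


def postprocess(mask: np.ndarray, cfg: PostprocessConfig | None = None) -> np.ndarray:
    """Hole filling, then opening+closing edge smoothing, then small-ROI
    removal, in that order."""
    cfg = (cfg or PostprocessConfig()).validate()
    out = np.asarray(mask, dtype=bool)
    if out.ndim != 2:
        raise InvalidInputError(f"mask must be 2-D, got shape {out.shape}")
    if cfg.fill_holes:
        # 8-connected foreground pairs with 4-connected background: holes
        # are flood-filled with the default 4-connectivity so a 1-px wall
        # still encloses them
        out = ndi.binary_fill_holes(out)
    if cfg.smooth_radius > 0:
        disk = morphology.disk(cfg.smooth_radius)
        out = morphology.closing(morphology.opening(out, disk), disk).astype(bool)
    if cfg.min_roi_area > 0:
        labels, _ = ndi.label(out, structure=_STRUCT8)
        sizes = np.bincount(labels.ravel())
        out = (labels > 0) & (sizes[labels] >= cfg.min_roi_area)
    return out


@dataclass
class PipelineReport:
    """Diagnostics from one pipeline run."""

    t1: int = 0
    t2: int = 0
    nc_actual: int = 0
    archive_size: int = 0
    timings: dict = field(default_factory=dict)


def run_pipeline(
    img: np.ndarray,
    swarm_cfg: SwarmConfig | None = None,
    sp_cfg: SuperpixelConfig | None = None,
    pp_cfg: PostprocessConfig | None = None,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, PipelineReport]:
    """Run the two-route segmentation pipeline on an RGB image.

    Route 1: pre-process -> swarm threshold search -> dark map I1.
    Route 2: superpixel clustering of the RGB image -> refinement by t1.
    The routes merge by union and the result is post-processed.

    Returns the final boolean mask and a report with the thresholds, the
    actual superpixel count, the final archive size and stage timings.
    """
    swarm_cfg = swarm_cfg or SwarmConfig()
    sp_cfg = sp_cfg or SuperpixelConfig()
    pp_cfg = pp_cfg or PostprocessConfig()
    report = PipelineReport()
    history: list = []

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        report.timings[name] = time.perf_counter() - t0
        return result

    ipre = _stage("preprocess", lambda: preprocess(img, clip_limit=clip_limit, tile_grid=tile_grid))
    thresholds = _stage("mopso", lambda: run_mmpso(ipre, swarm_cfg, rng=rng, history=history))
    t1, t2 = thresholds[0], thresholds[-1]
    report.t1, report.t2 = int(t1), int(t2)
    report.archive_size = len(history[-1]) if history else 0
    if len(thresholds) >= 2:
        i1, _, _ = _stage("apply_thresholds", lambda: apply_thresholds(ipre, t1, t2))
    else:  # k = 1: the dark map is simply the sub-threshold pixels
        i1 = _stage("apply_thresholds", lambda: ipre < t1)
    sp = _stage("superpixel", lambda: run_superpixel(img, sp_cfg))
    report.nc_actual = sp.nc_actual
    ithresh = _stage("refine", lambda: refine_clusters(sp, ipre, t1))
    merged = _stage("merge", lambda: merge_maps(i1, ithresh))
    out = _stage("postprocess", lambda: postprocess(merged, pp_cfg))
    return out, report
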