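"""Projected-area measurement of a sponge body from grayscale frames.

Reproduces the image-analysis step of the respirometry setup: the animal is
photographed against a dark background, each frame is segmented, and the
projected area in pixels (optionally calibrated to mm² with a ruler-derived
scale) becomes one sample of the behavioural area trace.

Segmentation is threshold-based: optional background subtraction, a global
Otsu threshold (a bimodal-histogram criterion), morphological closing,
largest connected component, hole filling.  The component boundary is the
detected edge; since the downstream quantity is the area, no explicit
gradient operator is needed (a gradient-based mode exists behind config).
Frames in which no object is found yield an explicit "no object" result
that propagates as a missing value in the trace — gaps are never silently
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "segment_frame",
    "calibrate_area",
    "frames_to_trace",
    "load_frame",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables for frame segmentation.

    ``min_contrast`` is the minimum foreground/background intensity
    separation (in intensity units) below which a frame is declared to
    contain no object; ``min_size`` discards specks smaller than that many
    pixels; ``closing_radius`` bridges small gaps along the body edge.
    ``mode`` selects "threshold" (default) or "gradient" (Sobel magnitude
    thresholded then filled).
    """

    closing_radius: int = 2
    min_size: int = 25
    min_contrast: float = 20.0
    background: Optional[np.ndarray] = None
    mode: str = "threshold"


@dataclass(frozen=True)
class SegmentationResult:
    mask: Optional[np.ndarray]
    area_pixels: int
    threshold: float
    area_mm2: Optional[float] = None

    @property
    def no_object(self) -> bool:
        return self.mask is None


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] < 16 or frame.shape[1] < 16:
        raise ValueError("frame must be a 2-D array of at least 16x16 pixels")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame intensities must be finite")
    return frame


def segment_frame(
    frame: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> SegmentationResult:
    """Segment the body and return its projected area in pixels."""
    img = _validate_frame(frame)
    if config.background is not None:
        img = img - np.asarray(config.background, dtype=float)

    if img.max() - img.min() < config.min_contrast:
        return SegmentationResult(mask=None, area_pixels=0, threshold=float("nan"))

    if config.mode == "gradient":
        edges = filters.sobel(img)
        thr = float(filters.threshold_otsu(edges))
        binary = edges > thr
        binary = morphology.closing(
            binary, morphology.disk(max(config.closing_radius, 1))
        )
        binary = ndimage.binary_fill_holes(binary)
        # the filled region extends to the outer rim of the edge band;
        # erode by one pixel to re-centre the boundary on the true edge
        binary = morphology.erosion(binary, morphology.disk(1))
    elif config.mode == "threshold":
        thr = float(filters.threshold_otsu(img))
        binary = img > thr
        if config.closing_radius > 0:
            binary = morphology.closing(
                binary, morphology.disk(config.closing_radius)
            )
    else:
        raise ValueError(f"unknown segmentation mode {config.mode!r}")

    labels, n = ndimage.label(binary)
    if n == 0:
        return SegmentationResult(mask=None, area_pixels=0, threshold=thr)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < config.min_size:
        return SegmentationResult(mask=None, area_pixels=0, threshold=thr)
    mask = ndimage.binary_fill_holes(labels == biggest)
    return SegmentationResult(
        mask=mask, area_pixels=int(mask.sum()), threshold=thr
    )


def calibrate_area(area_pixels: float, pixels_per_mm: float) -> float:
    """Convert a pixel area to mm² using a ruler-derived scale."""
    if pixels_per_mm <= 0:
        raise ValueError("pixels_per_mm must be > 0")
    return area_pixels / pixels_per_mm**2


def frames_to_trace(
    frames: Sequence[np.ndarray],
    timestamps_s: Sequence[float],
    config: SegmentationConfig = SegmentationConfig(),
    pixels_per_mm: Optional[float] = None,
) -> pd.DataFrame:
    """Per-frame projected area with timestamps.

    Returns a DataFrame (timestamp_s, area_px, area_mm2); frames with no
    detectable object carry NaN.  Timestamps must be strictly increasing.
    """
    ts = np.asarray(timestamps_s, dtype=float)
    if len(frames) != len(ts):
        raise ValueError("one timestamp per frame required")
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    areas = []
    for frame in frames:
        res = segment_frame(frame, config)
        areas.append(np.nan if res.no_object else float(res.area_pixels))
    out = pd.DataFrame({"timestamp_s": ts, "area_px": areas})
    if pixels_per_mm is not None:
        out["area_mm2"] = [
            calibrate_area(a, pixels_per_mm) if np.isfinite(a) else np.nan
            for a in out["area_px"]
        ]
    return out


def load_frame(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF frame as 2-D grayscale."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)
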