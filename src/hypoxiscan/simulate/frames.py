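"""Rendered frames of a bright sponge body on a dark background.

Emulates the photographic setup (animal against black felt): an 8-bit
grayscale ellipse of intensity ~200 on a ~30 background, whose area tracks
a supplied projected-area trace.  Sufficient for testing segmentation; no
optics are modelled.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

__all__ = ["render_frames", "ellipse_frame", "write_png_stack"]

BODY_INTENSITY = 200.0
BACKGROUND_INTENSITY = 30.0
ASPECT_RATIO = 1.5  # semi-major / semi-minor


def ellipse_frame(
    area_px: float,
    shape: tuple[int, int] = (120, 160),
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    angle_rad: float = 0.0,
) -> np.ndarray:
    """One 8-bit frame with a centred ellipse of the requested area."""
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("frame dimensions must be >= 16x16")
    a = math.sqrt(area_px * ASPECT_RATIO / math.pi)  # semi-major
    b = a / ASPECT_RATIO
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - (h - 1) / 2.0
    x = xx - (w - 1) / 2.0
    if angle_rad:
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        x, y = c * x + s * y, -s * x + c * y
    inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0 if area_px > 0 else np.zeros(
        (h, w), bool
    )
    img = np.where(inside, BODY_INTENSITY, BACKGROUND_INTENSITY)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_frames(
    areas_px: Sequence[float],
    shape: tuple[int, int] = (120, 160),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Render one frame per area sample."""
    rng = np.random.default_rng(seed)
    return [ellipse_frame(a, shape, noise_sd, rng) for a in areas_px]


def write_png_stack(frames: Sequence[np.ndarray], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = outdir / f"frame_{i:05d}.png"
        Image.fromarray(frame).save(p)
        paths.append(p)
    return paths
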