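"""Per-pixel multi-rater agreement maps and their rendered overlays.

An agreement map counts, for each pixel, how many of a subgroup's
annotators labelled that pixel. Rendering normalizes the counts by the
subgroup size, maps them through a sequential colormap, and overlays the
ground-truth ring (white) and the AI-prediction ring (black).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
from PIL import Image, ImageDraw

from .model import Group, ImageFrame, PolygonAnnotation, Round, as_polygon

__all__ = ["AgreementMap", "agreement_map", "render_heatmap", "DEFAULT_COLORMAP"]

DEFAULT_COLORMAP = "viridis"


@dataclass
class AgreementMap:
    image_id: str
    round: Round
    group: Group
    counts: np.ndarray  # (height, width) int raster
    n_annotators: int

    def __post_init__(self) -> None:
        if self.n_annotators < 1:
            raise ValueError("n_annotators must be >= 1")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_annotators:
            raise ValueError("counts must lie in [0, n_annotators]")


def agreement_map(
    masks: Sequence[np.ndarray],
    *,
    image_id: str,
    round: Round,
    group: Group,
    n_annotators: int | None = None,
) -> AgreementMap:
    """Stack member masks into a per-pixel vote count."""
    if not masks:
        raise ValueError("agreement map needs at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask dimensions differ: {shape} vs {m.shape}")
    counts = np.zeros(shape, dtype=np.int32)
    for m in masks:
        counts += m.astype(np.int32)
    return AgreementMap(
        image_id=image_id,
        round=round,
        group=group,
        counts=counts,
        n_annotators=n_annotators if n_annotators is not None else len(masks),
    )


def _ring_points(ann: PolygonAnnotation, frame: ImageFrame) -> list[tuple[float, float]]:
    poly = as_polygon(ann, frame)
    return list(poly.exterior.coords)


def render_heatmap(
    amap: AgreementMap,
    gt_ring: PolygonAnnotation,
    ai_ring: PolygonAnnotation,
    frame: ImageFrame,
    path: str | Path,
    *,
    colormap: str = DEFAULT_COLORMAP,
    contour_width: int = 2,
) -> Path:
    """Write the agreement map as a PNG with ground-truth and AI contours.

    Counts are normalized by the subgroup size (not the global max), so
    pre/post maps of one subgroup share a scale. Deterministic: identical
    inputs produce byte-identical files.
    """
    if amap.counts.shape != (frame.height, frame.width):
        raise ValueError("agreement map does not match the frame dimensions")
    cmap = matplotlib.colormaps[colormap]
    norm = amap.counts.astype(float) / amap.n_annotators
    rgb = cmap(norm, bytes=True)[..., :3]
    img = Image.fromarray(rgb, mode="RGB")
    draw = ImageDraw.Draw(img)
    draw.line(_ring_points(gt_ring, frame), fill=(255, 255, 255), width=contour_width)
    draw.line(_ring_points(ai_ring, frame), fill=(0, 0, 0), width=contour_width)
    path = Path(path)
    img.save(path, format="PNG")
    return path
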