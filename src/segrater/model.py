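"""Domain types for annotation studies: frames, polygon rings, binary masks.

Coordinate convention: origin at the top-left corner, x grows rightward,
y grows downward, units are pixels, coordinates are continuous. Pixel
(row r, column c) owns the half-open cell [c, c+1) x [r, r+1); membership
is tested at the pixel center (c + 0.5, r + 0.5).
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "Round",
    "Group",
    "ImageFrame",
    "PolygonAnnotation",
    "Annotator",
    "StudyDataset",
    "AnnotationError",
    "DegenerateAnnotationError",
    "SelfIntersectingRingError",
    "SchemaError",
    "MaskFormatError",
    "clean_ring",
    "clip_ring",
    "as_polygon",
    "rasterize",
    "load_dataset",
    "save_dataset",
    "read_mask",
    "write_mask",
]


class Round(str, enum.Enum):
    """Annotation round / provenance of a polygon."""

    PRE = "PRE"
    POST = "POST"
    GROUND_TRUTH = "GROUND_TRUTH"
    AI_PREDICTION = "AI_PREDICTION"


class Group(str, enum.Enum):
    """Annotator expertise subgroup."""

    STUDENT = "STUDENT"
    JUNIOR = "JUNIOR"
    INTERMEDIATE = "INTERMEDIATE"
    EXPERT = "EXPERT"


#: Canonical reporting order of the expertise subgroups.
GROUP_ORDER = (Group.STUDENT, Group.JUNIOR, Group.INTERMEDIATE, Group.EXPERT)


class AnnotationError(ValueError):
    """Base class for annotation geometry errors."""


class DegenerateAnnotationError(AnnotationError):
    """Ring has zero area (or fewer than 3 distinct vertices) after cleaning."""


class SelfIntersectingRingError(AnnotationError):
    """Ring is not simple; repaired silently nowhere — always rejected."""


class SchemaError(ValueError):
    """Annotation file violates the dataset schema."""


class MaskFormatError(ValueError):
    """Mask PNG is not a single-channel binary {0, 255} image."""


@dataclass(frozen=True)
class ImageFrame:
    image_id: str
    width: int
    height: int
    display_order: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"frame {self.image_id!r}: dimensions must be positive, "
                f"got {self.width}x{self.height}"
            )
        if self.display_order < 1:
            raise ValueError(f"frame {self.image_id!r}: display_order must be >= 1")


@dataclass(frozen=True)
class PolygonAnnotation:
    """One closed-ring outline drawn by one annotator on one image.

    ``vertices`` is an implicitly closed ring of ``(x, y)`` points in pixel
    coordinates; at least 3 vertices are required.
    """

    annotator_id: str
    image_id: str
    round: Round
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise DegenerateAnnotationError(
                f"annotation ({self.annotator_id}, {self.image_id}, "
                f"{self.round.value}): ring needs >= 3 vertices, "
                f"got {len(self.vertices)}"
            )
        object.__setattr__(
            self,
            "vertices",
            tuple((float(x), float(y)) for x, y in self.vertices),
        )

    @property
    def key(self) -> tuple[str, str, Round]:
        return (self.annotator_id, self.image_id, self.round)


@dataclass(frozen=True)
class Annotator:
    annotator_id: str
    group: Group


def clean_ring(
    vertices: Iterable[tuple[float, float]],
    *,
    context: str = "ring",
) -> np.ndarray:
    """Normalize a ring: drop an explicit closing vertex and consecutive
    duplicates. Returns an (n, 2) float array, n >= 3.

    Self-intersection is *not* repaired here; see :func:`as_polygon`.
    """
    pts = np.asarray(list(vertices), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateAnnotationError(f"{context}: vertices must be (n, 2)")
    # implicit closure: drop a duplicated last==first vertex
    if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if len(pts) < 3:
        raise DegenerateAnnotationError(
            f"{context}: fewer than 3 distinct vertices after cleaning"
        )
    return pts


def clip_ring(ring: np.ndarray, frame: ImageFrame, *, context: str = "ring") -> np.ndarray:
    """Clip vertices to [0, width] x [0, height], warning once if any moved."""
    clipped = np.column_stack(
        [np.clip(ring[:, 0], 0.0, frame.width), np.clip(ring[:, 1], 0.0, frame.height)]
    )
    if not np.array_equal(clipped, ring):
        logger.warning("%s: out-of-frame vertices clipped to %sx%s frame",
                       context, frame.width, frame.height)
    return clipped


def as_polygon(annotation: PolygonAnnotation, frame: ImageFrame | None = None) -> Polygon:
    """Cleaned (and, given a frame, clipped) shapely polygon for a ring.

    Raises :class:`SelfIntersectingRingError` for non-simple rings and
    :class:`DegenerateAnnotationError` for zero-area rings.
    """
    ctx = f"({annotation.annotator_id}, {annotation.image_id}, {annotation.round.value})"
    ring = clean_ring(annotation.vertices, context=ctx)
    if frame is not None:
        ring = clip_ring(ring, frame, context=ctx)
    poly = Polygon(ring)
    if not poly.is_valid:
        # zero-area invalidity (e.g. collinear ring) is degeneracy, not a
        # genuine crossing
        from shapely.validation import make_valid

        if make_valid(poly).area == 0:
            raise DegenerateAnnotationError(
                f"annotation {ctx}: zero area after cleaning"
            )
        raise SelfIntersectingRingError(f"annotation {ctx}: ring is not simple")
    if poly.area == 0:
        raise DegenerateAnnotationError(f"annotation {ctx}: zero area after cleaning")
    return poly


def rasterize(annotation: PolygonAnnotation, frame: ImageFrame) -> np.ndarray:
    """Rasterize a ring onto the frame's pixel grid.

    Pixel (r, c) is true iff its center (c + 0.5, r + 0.5) lies strictly
    inside the cleaned, clipped ring (even-odd rule; equivalently the
    interior of the simple polygon). Deterministic.
    """
    poly = as_polygon(annotation, frame)
    grid = np.zeros((frame.height, frame.width), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(frame.width, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(frame.height, int(np.ceil(maxy)))
    if c1 <= c0 or r1 <= r0:
        return grid
    xs = np.arange(c0, c1) + 0.5
    ys = np.arange(r0, r1) + 0.5
    X, Y = np.meshgrid(xs, ys)
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    grid[r0:r1, c0:c1] = inside
    return grid


# ---------------------------------------------------------------------------
# dataset container + GeoJSON-dialect I/O
# ---------------------------------------------------------------------------

PARTICIPANT_ROUNDS = (Round.PRE, Round.POST)


@dataclass
class StudyDataset:
    """All annotations of one comparative study."""

    frames: list[ImageFrame]
    annotators: list[Annotator]
    annotations: dict[tuple[str, str, Round], PolygonAnnotation] = field(default_factory=dict)
    ground_truth: dict[str, PolygonAnnotation] = field(default_factory=dict)
    ai_prediction: dict[str, PolygonAnnotation] = field(default_factory=dict)

    def frame(self, image_id: str) -> ImageFrame:
        for f in self.frames:
            if f.image_id == image_id:
                return f
        raise KeyError(image_id)

    @property
    def groups(self) -> dict[str, Group]:
        return {a.annotator_id: a.group for a in self.annotators}

    def completeness_report(self) -> list[tuple[str, str, Round]]:
        """Missing (annotator, image, round) participant entries."""
        missing = []
        for a in self.annotators:
            for f in self.frames:
                for rnd in PARTICIPANT_ROUNDS:
                    if (a.annotator_id, f.image_id, rnd) not in self.annotations:
                        missing.append((a.annotator_id, f.image_id, rnd))
        return missing

    def validate(self) -> None:
        ids = [f.image_id for f in self.frames]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate image_id in frames")
        for f in self.frames:
            if f.image_id not in self.ground_truth:
                raise SchemaError(f"frame {f.image_id!r}: missing ground truth")
            if f.image_id not in self.ai_prediction:
                raise SchemaError(f"frame {f.image_id!r}: missing AI prediction")
        known = set(ids)
        for key, ann in self.annotations.items():
            if ann.image_id not in known:
                raise SchemaError(f"annotation {key}: unknown image_id {ann.image_id!r}")


_CONSENSUS_ID = "consensus"
_AI_ID = "ai"


def _feature(ann: PolygonAnnotation, group: Group | None) -> dict:
    props = {
        "annotator_id": ann.annotator_id,
        "image_id": ann.image_id,
        "round": ann.round.value,
    }
    if group is not None:
        props["group"] = group.value
    ring = [[x, y] for x, y in ann.vertices]
    ring.append(list(ring[0]))
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": props,
    }


def save_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write the GeoJSON-dialect annotation file (FeatureCollection plus a
    top-level ``frames`` foreign member)."""
    groups = dataset.groups
    features = []
    for f in dataset.frames:
        features.append(_feature(dataset.ground_truth[f.image_id], None))
        features.append(_feature(dataset.ai_prediction[f.image_id], None))
    for key in sorted(dataset.annotations, key=lambda k: (k[0], k[1], k[2].value)):
        ann = dataset.annotations[key]
        features.append(_feature(ann, groups[ann.annotator_id]))
    doc = {
        "type": "FeatureCollection",
        "frames": [
            {
                "image_id": f.image_id,
                "width": f.width,
                "height": f.height,
                "display_order": f.display_order,
            }
            for f in dataset.frames
        ],
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _parse_feature(feat: dict, frames: Mapping[str, ImageFrame]) -> tuple[PolygonAnnotation, Group | None]:
    props = feat.get("properties") or {}
    geom = feat.get("geometry") or {}
    if geom.get("type") != "Polygon":
        raise SchemaError(f"feature {props}: geometry must be Polygon")
    coords = geom.get("coordinates") or []
    if len(coords) != 1:
        raise SchemaError(f"feature {props}: exactly one exterior ring required (no holes)")
    for name in ("annotator_id", "image_id", "round"):
        if name not in props:
            raise SchemaError(f"feature missing property {name!r}: {props}")
    try:
        rnd = Round(props["round"])
    except ValueError as exc:
        raise SchemaError(f"unknown round {props['round']!r}") from exc
    image_id = props["image_id"]
    if image_id not in frames:
        raise SchemaError(f"feature references unknown image_id {image_id!r}")
    ctx = f"({props['annotator_id']}, {image_id}, {rnd.value})"
    try:
        ring = clean_ring(coords[0], context=ctx)
    except DegenerateAnnotationError as exc:
        raise SchemaError(str(exc)) from exc
    ring = clip_ring(ring, frames[image_id], context=ctx)
    ann = PolygonAnnotation(
        annotator_id=props["annotator_id"],
        image_id=image_id,
        round=rnd,
        vertices=tuple(map(tuple, ring)),
    )
    group: Group | None = None
    if rnd in PARTICIPANT_ROUNDS:
        if "group" not in props:
            raise SchemaError(f"participant feature {ctx} missing group")
        try:
            group = Group(props["group"])
        except ValueError as exc:
            raise SchemaError(f"unknown group label {props['group']!r}") from exc
    return ann, group


def load_dataset(path: str | Path) -> StudyDataset:
    """Load and validate a GeoJSON-dialect annotation file.

    Rings are cleaned and clipped on load (warning per modified ring).
    Missing PRE/POST pairs do not fail the load; they are reported by
    :meth:`StudyDataset.completeness_report`.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("not a FeatureCollection")
    if "frames" not in doc:
        raise SchemaError("missing top-level 'frames' member")
    frames = [
        ImageFrame(
            image_id=f["image_id"],
            width=int(f["width"]),
            height=int(f["height"]),
            display_order=int(f.get("display_order", i + 1)),
        )
        for i, f in enumerate(doc["frames"])
    ]
    frame_map = {f.image_id: f for f in frames}
    if len(frame_map) != len(frames):
        raise SchemaError("duplicate image_id in frames")

    dataset = StudyDataset(frames=frames, annotators=[])
    seen_groups: dict[str, Group] = {}
    for feat in doc.get("features", []):
        ann, group = _parse_feature(feat, frame_map)
        if ann.round is Round.GROUND_TRUTH:
            dataset.ground_truth[ann.image_id] = ann
        elif ann.round is Round.AI_PREDICTION:
            dataset.ai_prediction[ann.image_id] = ann
        else:
            assert group is not None
            prev = seen_groups.setdefault(ann.annotator_id, group)
            if prev is not group:
                raise SchemaError(
                    f"annotator {ann.annotator_id!r}: inconsistent group labels "
                    f"{prev.value} vs {group.value}"
                )
            dataset.annotations[ann.key] = ann
    dataset.annotators = [
        Annotator(aid, grp) for aid, grp in sorted(seen_groups.items())
    ]
    dataset.validate()
    missing = dataset.completeness_report()
    if missing:
        logger.warning("dataset %s: %d missing participant annotations", path, len(missing))
    return dataset


# ---------------------------------------------------------------------------
# mask PNG I/O
# ---------------------------------------------------------------------------


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel PNG (0 background, 255 label)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise MaskFormatError("mask must be a 2-D boolean array")
    Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(path, format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel binary {0, 255} PNG back into a boolean mask."""
    with Image.open(path) as img:
        if img.mode != "L":
            raise MaskFormatError(f"{path}: expected single-channel (L) PNG, got {img.mode}")
        arr = np.asarray(img)
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise MaskFormatError(f"{path}: non-binary pixel values {bad.tolist()}")
    return arr == 255
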