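"""Seeded generator of a full synthetic annotation study.

Ground-truth outlines are star-convex radial shapes (ellipse modulated by
low-order harmonics), AI predictions are radial perturbations calibrated by
bisection to a target DICE, and annotator behaviour is modelled per
expertise subgroup: boundary noise and centre offset in the unassisted
round, then probabilistic adoption of a radial blend toward the AI outline
in the assisted round. Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .metrics import dice, overlap_counts
from .model import (
    GROUP_ORDER,
    Annotator,
    Group,
    ImageFrame,
    PolygonAnnotation,
    Round,
    StudyDataset,
    as_polygon,
    rasterize,
)

__all__ = [
    "RING_SAMPLES",
    "ShapeParams",
    "AnnotatorProfile",
    "GroupSpec",
    "StudyConfig",
    "ConvergenceError",
    "DEFAULT_PROFILES",
    "default_config",
    "generate_gt_shape",
    "generate_ai_prediction",
    "simulate_annotation_pre",
    "simulate_annotation_post",
    "generate_study",
    "radial_profile",
    "load_config",
    "save_config",
]

#: ring sample count — sub-pixel angular resolution at the default frame
RING_SAMPLES = 360


class ConvergenceError(RuntimeError):
    """AI-quality bisection failed to reach the target DICE band."""


@dataclass(frozen=True)
class ShapeParams:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    n_harmonics: int = 4
    harmonic_amp_max: float = 0.15

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0.0 <= self.harmonic_amp_max < 1.0:
            raise ValueError("harmonic_amp_max must be in [0, 1) to keep r > 0")


@dataclass(frozen=True)
class AnnotatorProfile:
    group: Group
    boundary_noise_sd: float  # fraction of local radius
    center_offset_sd: float  # pixels
    adoption_prob: float
    blend_weight: float  # weight on the AI outline when adopting

    def __post_init__(self) -> None:
        if self.boundary_noise_sd < 0 or self.center_offset_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        for name in ("adoption_prob", "blend_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GroupSpec:
    n_annotators: int
    profile: AnnotatorProfile

    def __post_init__(self) -> None:
        if self.n_annotators < 1:
            raise ValueError("each group needs at least one annotator")


@dataclass(frozen=True)
class StudyConfig:
    seed: int
    n_images: int = 6
    frame_width: int = 720
    frame_height: int = 576
    ai_target_dice: float = 0.85
    ai_tolerance: float = 0.02
    groups: dict[Group, GroupSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0.0 < self.ai_target_dice <= 1.0:
            raise ValueError("ai_target_dice must be in (0, 1]")
        if not self.groups:
            raise ValueError("at least one group required")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_images": self.n_images,
            "frame": {"width": self.frame_width, "height": self.frame_height},
            "ai_target_dice": self.ai_target_dice,
            "ai_tolerance": self.ai_tolerance,
            "groups": {
                g.value: {
                    "n_annotators": spec.n_annotators,
                    "boundary_noise_sd": spec.profile.boundary_noise_sd,
                    "center_offset_sd": spec.profile.center_offset_sd,
                    "adoption_prob": spec.profile.adoption_prob,
                    "blend_weight": spec.profile.blend_weight,
                }
                for g, spec in self.groups.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        frame = d.get("frame", {})
        groups = {}
        for gname, spec in d["groups"].items():
            g = Group(gname)
            groups[g] = GroupSpec(
                n_annotators=int(spec["n_annotators"]),
                profile=AnnotatorProfile(
                    group=g,
                    boundary_noise_sd=float(spec["boundary_noise_sd"]),
                    center_offset_sd=float(spec["center_offset_sd"]),
                    adoption_prob=float(spec["adoption_prob"]),
                    blend_weight=float(spec["blend_weight"]),
                ),
            )
        return cls(
            seed=int(d["seed"]),
            n_images=int(d.get("n_images", 6)),
            frame_width=int(frame.get("width", 720)),
            frame_height=int(frame.get("height", 576)),
            ai_target_dice=float(d.get("ai_target_dice", 0.85)),
            ai_tolerance=float(d.get("ai_tolerance", 0.02)),
            groups=groups,
        )


#: Documented default behaviour profiles: boundary noise and centre offset
#: decrease with expertise, while AI adoption and blend weight decrease with
#: expertise — non-experts both err more and lean on the AI more.
DEFAULT_PROFILES: dict[Group, AnnotatorProfile] = {
    Group.STUDENT: AnnotatorProfile(Group.STUDENT, 0.30, 12.0, 0.95, 0.90),
    Group.JUNIOR: AnnotatorProfile(Group.JUNIOR, 0.25, 10.0, 0.80, 0.80),
    Group.INTERMEDIATE: AnnotatorProfile(Group.INTERMEDIATE, 0.22, 8.0, 0.55, 0.65),
    Group.EXPERT: AnnotatorProfile(Group.EXPERT, 0.20, 6.0, 0.30, 0.50),
}


def default_config(
    seed: int,
    *,
    n_images: int = 6,
    frame_width: int = 720,
    frame_height: int = 576,
    n_per_group: int = 6,
    ai_target_dice: float = 0.85,
    ai_tolerance: float = 0.02,
) -> StudyConfig:
    """The default study layout: 4 expertise groups x 6 annotators x 6 images."""
    return StudyConfig(
        seed=seed,
        n_images=n_images,
        frame_width=frame_width,
        frame_height=frame_height,
        ai_target_dice=ai_target_dice,
        ai_tolerance=ai_tolerance,
        groups={g: GroupSpec(n_per_group, DEFAULT_PROFILES[g]) for g in GROUP_ORDER},
    )


def load_config(path: str | Path) -> StudyConfig:
    return StudyConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def save_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# radial geometry helpers
# ---------------------------------------------------------------------------

_ANGLES = 2.0 * np.pi * np.arange(RING_SAMPLES) / RING_SAMPLES


def _smooth_noise(rng: np.random.Generator, angles: np.ndarray, n_harmonics: int = 6) -> np.ndarray:
    """Unit-RMS smooth periodic noise: a random low-order harmonic mixture."""
    g = np.zeros_like(angles)
    for k in range(1, n_harmonics + 1):
        amp = rng.normal(0.0, 1.0 / k)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        g += amp * np.cos(k * angles + phase)
    rms = np.sqrt(np.mean(g**2))
    if rms < 1e-12:
        return np.zeros_like(angles)
    return g / rms


def radial_profile(
    vertices: np.ndarray, center: tuple[float, float], angles: np.ndarray
) -> np.ndarray:
    """Distance from ``center`` to the ring boundary along each angle.

    Ray-casts against every edge and keeps the farthest intersection, which
    resamples arbitrary simple rings into a star-convex radial profile
    about ``center``. Angles whose ray misses the ring entirely get 0.
    """
    v1 = np.asarray(vertices, dtype=float)
    v2 = np.roll(v1, -1, axis=0)
    e = v2 - v1  # (m, 2)
    d = np.column_stack([np.cos(angles), np.sin(angles)])  # (k, 2)
    w = v1 - np.asarray(center, dtype=float)  # (m, 2)
    # ray c + t*d meets segment v1 + s*e where cross(d, e) != 0
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]  # (k, m)
    cross_we = w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]
    cross_wd = w[None, :, 0] * d[:, None, 1] - w[None, :, 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        # t = cross(w, e) / cross(d, e); s = cross(w, d) / cross(d, e)
        t = np.where(np.abs(denom) > 1e-12, cross_we / denom, -np.inf)
        s = np.where(np.abs(denom) > 1e-12, cross_wd / denom, -1.0)
    valid = (t > 0) & (s >= 0.0) & (s <= 1.0)
    t = np.where(valid, t, 0.0)
    return t.max(axis=1)


def _ring_annotation(
    center: tuple[float, float],
    radii: np.ndarray,
    *,
    annotator_id: str,
    image_id: str,
    round: Round,
) -> PolygonAnnotation:
    xs = center[0] + radii * np.cos(_ANGLES)
    ys = center[1] + radii * np.sin(_ANGLES)
    return PolygonAnnotation(
        annotator_id=annotator_id,
        image_id=image_id,
        round=round,
        vertices=tuple(zip(xs.tolist(), ys.tolist())),
    )


def _centroid(ann: PolygonAnnotation) -> tuple[float, float]:
    c = as_polygon(ann).centroid
    return (c.x, c.y)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_gt_shape(
    rng: np.random.Generator,
    frame: ImageFrame,
    params: ShapeParams,
    *,
    image_id: str | None = None,
) -> PolygonAnnotation:
    """Sample a star-convex ground-truth ring.

    r(theta) = r_ellipse(theta) * (1 + sum_k a_k cos(k theta + phi_k)),
    sampled at RING_SAMPLES equal angles; positive r makes the ring
    star-convex about the centre by construction.
    """
    a, b = params.semi_axes
    r_ell = a * b / np.sqrt((b * np.cos(_ANGLES)) ** 2 + (a * np.sin(_ANGLES)) ** 2)
    mod = np.ones_like(_ANGLES)
    if params.n_harmonics > 0 and params.harmonic_amp_max > 0:
        per_harm = params.harmonic_amp_max / params.n_harmonics
        for k in range(1, params.n_harmonics + 1):
            amp = rng.uniform(0.0, per_harm)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            mod += amp * np.cos(k * _ANGLES + phase)
    radii = r_ell * mod
    cx, cy = params.center
    xs = cx + radii * np.cos(_ANGLES)
    ys = cy + radii * np.sin(_ANGLES)
    if xs.min() < 0 or ys.min() < 0 or xs.max() > frame.width or ys.max() > frame.height:
        raise ValueError(
            f"ground-truth shape exceeds the {frame.width}x{frame.height} frame"
        )
    return _ring_annotation(
        (cx, cy), radii,
        annotator_id="consensus",
        image_id=image_id or frame.image_id,
        round=Round.GROUND_TRUTH,
    )


def _mask_dice(a: np.ndarray, b: np.ndarray) -> float:
    return dice(overlap_counts(a, b))


def generate_ai_prediction(
    gt: PolygonAnnotation,
    frame: ImageFrame,
    target_dice: float,
    tol: float,
    rng: np.random.Generator,
    *,
    max_iter: int = 60,
) -> PolygonAnnotation:
    """Perturb the ground truth until its rasterized DICE hits the target band.

    A single smooth noise field g is drawn; the amplitude A of the radial
    perturbation r -> r * (1 + A g) is found by bracketing and bisection so
    that dice(gt, prediction) lies in [target - tol, target + tol].
    A target of exactly 1.0 returns an unperturbed copy.
    """
    if not 0.0 < target_dice <= 1.0:
        raise ValueError("target_dice must be in (0, 1]")
    center = _centroid(gt)
    verts = np.asarray(gt.vertices)
    radii = radial_profile(verts, center, _ANGLES)
    if target_dice >= 1.0:
        return _ring_annotation(
            center, radii, annotator_id="ai", image_id=gt.image_id,
            round=Round.AI_PREDICTION,
        )
    gt_mask = rasterize(gt, frame)
    g = _smooth_noise(rng, _ANGLES)

    def candidate(amp: float) -> PolygonAnnotation:
        r = np.maximum(radii * (1.0 + amp * g), 2.0)
        return _ring_annotation(
            center, r, annotator_id="ai", image_id=gt.image_id,
            round=Round.AI_PREDICTION,
        )

    def achieved(amp: float) -> tuple[float, PolygonAnnotation]:
        cand = candidate(amp)
        return _mask_dice(gt_mask, rasterize(cand, frame)), cand

    lo, hi = 0.0, 0.05
    d_hi, cand = achieved(hi)
    expansions = 0
    while d_hi > target_dice + tol:
        lo, hi = hi, hi * 1.7
        d_hi, cand = achieved(hi)
        expansions += 1
        if expansions > 30:
            raise ConvergenceError(
                f"image {gt.image_id}: cannot reach dice {target_dice} by expansion"
            )
    if d_hi >= target_dice - tol:
        return cand
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid, cand = achieved(mid)
        if target_dice - tol <= d_mid <= target_dice + tol:
            return cand
        if d_mid > target_dice:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError(
        f"image {gt.image_id}: bisection did not reach dice "
        f"{target_dice}±{tol} in {max_iter} iterations"
    )


def simulate_annotation_pre(
    gt: PolygonAnnotation,
    frame: ImageFrame,
    profile: AnnotatorProfile,
    rng: np.random.Generator,
    *,
    annotator_id: str,
) -> PolygonAnnotation:
    """Round-1 (unassisted) annotation: radial boundary noise plus a
    Gaussian centre offset, clipped to the frame."""
    center = _centroid(gt)
    radii = radial_profile(np.asarray(gt.vertices), center, _ANGLES)
    g = _smooth_noise(rng, _ANGLES)
    noisy = np.maximum(radii * (1.0 + profile.boundary_noise_sd * g), 2.0)
    offset = rng.normal(0.0, profile.center_offset_sd, size=2)
    new_center = (center[0] + offset[0], center[1] + offset[1])
    xs = np.clip(new_center[0] + noisy * np.cos(_ANGLES), 0.0, frame.width)
    ys = np.clip(new_center[1] + noisy * np.sin(_ANGLES), 0.0, frame.height)
    return PolygonAnnotation(
        annotator_id=annotator_id,
        image_id=gt.image_id,
        round=Round.PRE,
        vertices=tuple(zip(xs.tolist(), ys.tolist())),
    )


def simulate_annotation_post(
    pre: PolygonAnnotation,
    ai: PolygonAnnotation,
    frame: ImageFrame,
    profile: AnnotatorProfile,
    rng: np.random.Generator,
) -> PolygonAnnotation:
    """Round-2 (AI-assisted) annotation.

    With probability ``adoption_prob`` the radial profile about the pre
    annotation's centre is blended toward the AI outline (weight
    ``blend_weight``); otherwise the pre annotation is kept verbatim.
    """
    adopt = rng.random() < profile.adoption_prob
    if not adopt:
        return PolygonAnnotation(
            annotator_id=pre.annotator_id,
            image_id=pre.image_id,
            round=Round.POST,
            vertices=pre.vertices,
        )
    if profile.blend_weight >= 1.0:
        # full adoption: exact copy of the AI outline (radial resampling
        # about the pre centre would only approximate it)
        return PolygonAnnotation(
            annotator_id=pre.annotator_id,
            image_id=pre.image_id,
            round=Round.POST,
            vertices=ai.vertices,
        )
    center = _centroid(pre)
    r_pre = radial_profile(np.asarray(pre.vertices), center, _ANGLES)
    r_ai = radial_profile(np.asarray(ai.vertices), center, _ANGLES)
    # rays that miss the AI ring (centre far outside it) fall back to pre
    r_ai = np.where(r_ai > 0, r_ai, r_pre)
    w = profile.blend_weight
    blended = w * r_ai + (1.0 - w) * r_pre
    xs = np.clip(center[0] + blended * np.cos(_ANGLES), 0.0, frame.width)
    ys = np.clip(center[1] + blended * np.sin(_ANGLES), 0.0, frame.height)
    return PolygonAnnotation(
        annotator_id=pre.annotator_id,
        image_id=pre.image_id,
        round=Round.POST,
        vertices=tuple(zip(xs.tolist(), ys.tolist())),
    )


def _sample_shape_params(
    rng: np.random.Generator, frame: ImageFrame
) -> ShapeParams:
    w, h = frame.width, frame.height
    cx = w / 2 + rng.uniform(-0.04 * w, 0.04 * w)
    cy = h / 2 + rng.uniform(-0.04 * h, 0.04 * h)
    a = rng.uniform(0.14, 0.19) * w
    b = rng.uniform(0.16, 0.22) * h
    return ShapeParams(center=(cx, cy), semi_axes=(a, b))


def generate_study(config: StudyConfig) -> StudyDataset:
    """Generate the full synthetic study deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    frames = [
        ImageFrame(
            image_id=f"img{i + 1:02d}",
            width=config.frame_width,
            height=config.frame_height,
            display_order=i + 1,
        )
        for i in range(config.n_images)
    ]
    dataset = StudyDataset(frames=frames, annotators=[])
    for frame in frames:
        params = _sample_shape_params(rng, frame)
        gt = generate_gt_shape(rng, frame, params)
        ai = generate_ai_prediction(
            gt, frame, config.ai_target_dice, config.ai_tolerance, rng
        )
        dataset.ground_truth[frame.image_id] = gt
        dataset.ai_prediction[frame.image_id] = ai

    for group in GROUP_ORDER:
        if group not in config.groups:
            continue
        spec = config.groups[group]
        for i in range(spec.n_annotators):
            aid = f"{group.value.lower()}_{i + 1:02d}"
            dataset.annotators.append(Annotator(aid, group))
            for frame in frames:
                gt = dataset.ground_truth[frame.image_id]
                ai = dataset.ai_prediction[frame.image_id]
                pre = simulate_annotation_pre(
                    gt, frame, spec.profile, rng, annotator_id=aid
                )
                post = simulate_annotation_post(pre, ai, frame, spec.profile, rng)
                dataset.annotations[pre.key] = pre
                dataset.annotations[post.key] = post
    dataset.validate()
    return dataset
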