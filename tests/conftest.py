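from __future__ import annotations

import numpy as np
import pytest

from segrater.model import (
    Annotator,
    Group,
    ImageFrame,
    PolygonAnnotation,
    Round,
    StudyDataset,
)


def ring(points, *, annotator_id="a", image_id="img01", round=Round.PRE):
    return PolygonAnnotation(
        annotator_id=annotator_id, image_id=image_id, round=round,
        vertices=tuple(points),
    )


def rect_ring(x0, y0, x1, y1, **kw):
    return ring([(x0, y0), (x1, y0), (x1, y1), (x0, y1)], **kw)


def rect_mask(frame: ImageFrame, x0, y0, x1, y1):
    """Closed-form rasterization of an integer-corner rectangle."""
    m = np.zeros((frame.height, frame.width), dtype=bool)
    m[int(y0):int(y1), int(x0):int(x1)] = True
    return m


@pytest.fixture
def frame10():
    return ImageFrame("img01", 10, 10)


@pytest.fixture
def frame20():
    return ImageFrame("img01", 20, 20)


def tiny_dataset(*, drop_one_post: bool = False) -> StudyDataset:
    """2 frames x 2 annotators, complete PRE/POST, plus GT and AI rings."""
    frames = [ImageFrame("img01", 50, 40, 1), ImageFrame("img02", 50, 40, 2)]
    annotators = [Annotator("s1", Group.STUDENT), Annotator("e1", Group.EXPERT)]
    ds = StudyDataset(frames=frames, annotators=annotators)
    for f in frames:
        ds.ground_truth[f.image_id] = rect_ring(
            10, 10, 30, 30, annotator_id="consensus", image_id=f.image_id,
            round=Round.GROUND_TRUTH)
        ds.ai_prediction[f.image_id] = rect_ring(
            12, 10, 32, 30, annotator_id="ai", image_id=f.image_id,
            round=Round.AI_PREDICTION)
    for a in annotators:
        for f in frames:
            for rnd, off in ((Round.PRE, 4), (Round.POST, 2)):
                if drop_one_post and (a.annotator_id, f.image_id, rnd) == (
                        "e1", "img02", Round.POST):
                    continue
                ds.annotations[(a.annotator_id, f.image_id, rnd)] = rect_ring(
                    10 + off, 10, 30 + off, 30,
                    annotator_id=a.annotator_id, image_id=f.image_id, round=rnd)
    return ds


@pytest.fixture
def dataset2x2():
    return tiny_dataset()
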