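"""Orchestration: simulate -> evaluate -> report, plus the run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .heatmap import DEFAULT_COLORMAP, agreement_map, render_heatmap
from .metrics import (
    ChangeRecord,
    MetricRecord,
    Outcome,
    classify_change,
    evaluate_annotation,
)
from .model import (
    GROUP_ORDER,
    Group,
    Round,
    StudyDataset,
    load_dataset,
    rasterize,
    save_dataset,
)
from .stats import StudySummary, summarize_study
from .synthetic import StudyConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "EvaluationResult",
    "evaluate_dataset",
    "records_frame",
    "records_from_frame",
    "write_summary",
    "run_pipeline",
]

_METRIC_COLUMNS = [
    "annotator_id", "group", "image_id", "round",
    "dice", "fp_pct", "fn_pct", "centroid_hit", "changed", "outcome",
]


@dataclass
class PipelineConfig:
    out_dir: Path
    study_config: StudyConfig | None = None
    dataset_path: Path | None = None
    colormap: str = DEFAULT_COLORMAP
    precision: int = 3
    seed: int | None = None  # overrides study_config.seed when given

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.precision < 1:
            raise ValueError("report precision must be >= 1")
        if (self.study_config is None) == (self.dataset_path is None):
            raise ValueError("exactly one of study_config / dataset_path required")


@dataclass
class EvaluationResult:
    records: list[MetricRecord]
    changes: list[ChangeRecord]
    errors: list[str] = field(default_factory=list)


def evaluate_dataset(dataset: StudyDataset) -> EvaluationResult:
    """Score every complete PRE/POST pair against ground truth.

    Per-annotation failures (degenerate rings, ...) are collected rather
    than aborting the run; they are reported once with counts.
    """
    records: list[MetricRecord] = []
    changes: list[ChangeRecord] = []
    errors: list[str] = []
    gt_masks = {
        f.image_id: rasterize(dataset.ground_truth[f.image_id], f)
        for f in dataset.frames
    }
    for annotator in dataset.annotators:
        for frame in dataset.frames:
            key_pre = (annotator.annotator_id, frame.image_id, Round.PRE)
            key_post = (annotator.annotator_id, frame.image_id, Round.POST)
            pair = []
            for key in (key_pre, key_post):
                ann = dataset.annotations.get(key)
                if ann is None:
                    errors.append(f"missing annotation {key}")
                    continue
                try:
                    mask = rasterize(ann, frame)
                except ValueError as exc:
                    errors.append(str(exc))
                    continue
                rec = evaluate_annotation(
                    gt_masks[frame.image_id], mask,
                    annotator_id=annotator.annotator_id,
                    image_id=frame.image_id,
                    round=key[2].value,
                )
                logger.debug("scored %s: dice=%.4f", key, rec.dice)
                records.append(rec)
                pair.append((mask, rec))
            if len(pair) == 2:
                changes.append(classify_change(pair[0], pair[1]))
    if errors:
        logger.warning("evaluation skipped %d annotations: %s", len(errors), errors[:5])
    return EvaluationResult(records=records, changes=changes, errors=errors)


def records_frame(result: EvaluationResult, groups: dict[str, Group]) -> pd.DataFrame:
    """Per-annotation metrics as a flat table (percent scale for fp/fn)."""
    change_map = {(c.annotator_id, c.image_id): c for c in result.changes}
    rows = []
    for rec in result.records:
        ch = change_map.get((rec.annotator_id, rec.image_id))
        rows.append({
            "annotator_id": rec.annotator_id,
            "group": groups[rec.annotator_id].value,
            "image_id": rec.image_id,
            "round": rec.round,
            "dice": rec.dice,
            "fp_pct": 100.0 * rec.fp_frac,
            "fn_pct": 100.0 * rec.fn_frac,
            "centroid_hit": rec.centroid_hit,
            "changed": ch.annotation_changed if ch else None,
            "outcome": ch.dice_outcome.value if ch else None,
        })
    df = pd.DataFrame(rows, columns=_METRIC_COLUMNS)
    return df.sort_values(["annotator_id", "image_id", "round"], ignore_index=True)


def records_from_frame(df: pd.DataFrame) -> tuple[list[MetricRecord], list[ChangeRecord], dict[str, Group]]:
    """Inverse of :func:`records_frame` (for the report-from-CSV path)."""
    records, seen_changes = [], {}
    groups: dict[str, Group] = {}
    for row in df.itertuples(index=False):
        groups[row.annotator_id] = Group(row.group)
        records.append(MetricRecord(
            annotator_id=row.annotator_id,
            image_id=row.image_id,
            round=str(row.round),
            dice=float(row.dice),
            fp_frac=float(row.fp_pct) / 100.0,
            fn_frac=float(row.fn_pct) / 100.0,
            centroid_hit=bool(row.centroid_hit),
        ))
        if row.changed is not None and not pd.isna(row.changed):
            seen_changes[(row.annotator_id, row.image_id)] = ChangeRecord(
                annotator_id=row.annotator_id,
                image_id=row.image_id,
                annotation_changed=bool(row.changed),
                dice_outcome=Outcome(row.outcome),
            )
    return records, list(seen_changes.values()), groups


def write_summary(summary: StudySummary, out_dir: Path, precision: int = 3) -> list[str]:
    """Write table CSVs (full precision) and a rounded plain-text report."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "table1.csv": summary.table1,
        "table2.csv": summary.table2,
        "table3.csv": summary.table3,
        "change_summary.csv": summary.change_summary,
        "participant_centroid.csv": summary.participant_centroid,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / name, index=False)
        written.append(name)
    lines = []
    for name, df in tables.items():
        lines.append(f"== {name[:-4]} ==")
        lines.append(df.round(precision).to_string(index=False))
        lines.append("")
    (out_dir / "report.txt").write_text("\n".join(lines))
    written.append("report.txt")
    return written


def _library_versions() -> dict[str, str]:
    import matplotlib
    import PIL
    import scipy
    import shapely

    return {
        "segrater": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "shapely": shapely.__version__,
        "pillow": PIL.__version__,
        "matplotlib": matplotlib.__version__,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Full simulate/load -> evaluate -> report run.

    Writes per-annotation metrics, the summary tables, one agreement heat
    map per (group, image, round), and a manifest that suffices to re-run
    the pipeline bit-identically. Returns the manifest.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    if config.dataset_path is not None:
        dataset = load_dataset(config.dataset_path)
        source = {"dataset_path": str(config.dataset_path)}
    else:
        sc = config.study_config
        if config.seed is not None and config.seed != sc.seed:
            sc = StudyConfig.from_dict({**sc.to_dict(), "seed": config.seed})
        dataset = generate_study(sc)
        save_dataset(dataset, out / "dataset.json")
        outputs.append("dataset.json")
        source = {"study_config": sc.to_dict()}

    result = evaluate_dataset(dataset)
    groups = dataset.groups
    df = records_frame(result, groups)
    df.to_csv(out / "metrics.csv", index=False)
    outputs.append("metrics.csv")

    summary = summarize_study(result.records, result.changes, groups)
    outputs += write_summary(summary, out, config.precision)

    heat_dir = out / "heatmaps"
    heat_dir.mkdir(exist_ok=True)
    masks_by_key: dict[tuple[str, str, Round], np.ndarray] = {}
    for frame in dataset.frames:
        for g in GROUP_ORDER:
            members = [a for a in dataset.annotators if a.group is g]
            if not members:
                continue
            for rnd in (Round.PRE, Round.POST):
                masks = []
                for a in members:
                    ann = dataset.annotations.get((a.annotator_id, frame.image_id, rnd))
                    if ann is not None:
                        masks.append(rasterize(ann, frame))
                if not masks:
                    continue
                amap = agreement_map(
                    masks, image_id=frame.image_id, round=rnd, group=g,
                    n_annotators=len(members),
                )
                name = f"{g.value}_{frame.image_id}_{rnd.value}.png"
                render_heatmap(
                    amap,
                    dataset.ground_truth[frame.image_id],
                    dataset.ai_prediction[frame.image_id],
                    frame,
                    heat_dir / name,
                    colormap=config.colormap,
                )
                outputs.append(f"heatmaps/{name}")

    manifest = {
        "source": source,
        "seed": config.seed,
        "colormap": config.colormap,
        "precision": config.precision,
        "versions": _library_versions(),
        "n_records": len(result.records),
        "n_skipped": len(result.errors),
        "n_heatmaps": sum(1 for o in outputs if o.startswith("heatmaps/")),
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
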