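# segrater

Multi-rater segmentation study toolkit: score polygon annotations of an
anatomical structure against a consensus ground truth, compare an
unassisted round with an AI-assisted round using exact paired statistics,
and render per-subgroup agreement heat maps. A seeded synthetic-study
generator emulates the full study design (expertise groups × annotators ×
images × two rounds), so every stage runs and is testable without any
private raw data.

## What it computes

- **Rasterization** — closed polygon rings are rasterized on the image
  pixel grid (pixel-center membership, even-odd rule); rings are cleaned
  (duplicate vertices dropped, implicit closure) and clipped to the frame,
  while self-intersecting rings are rejected rather than silently repaired.
- **Per-annotation metrics** — DICE overlap, false-positive and
  false-negative areas as fractions of the union |GT ∪ P|, inclusion of the
  ground-truth centroid, and pre/post change classification
  (changed / improved / worsened / unchanged).
- **Statistics** — exact two-sided Wilcoxon signed-rank (full enumeration
  of the signed-rank distribution, mid-ranks for ties, zeros dropped;
  normal approximation beyond n = 25), Fisher's exact test
  (minimum-likelihood two-sided), exact binomial McNemar, and the summary
  tables: centroid inclusion, mean DICE, FP/FN error analysis, change
  summary, and per-participant centroid analysis.
- **Agreement heat maps** — per (group, image, round) pixel vote counts,
  normalized by subgroup size, rendered with ground-truth (white) and AI
  (black) contours.
- **Synthetic studies** — star-convex radial ground-truth shapes, AI
  predictions calibrated by bisection to a target DICE, and per-group
  annotator behaviour (boundary noise, centre offset, probabilistic
  adoption of a radial blend toward the AI outline).

## CLI

```sh
# full pipeline with the built-in default study layout (4 groups x 6
# annotators x 6 images, AI target DICE 0.85)
segrater run --seed 7 --out out/

# or stage by stage, with a YAML config
segrater simulate --config study.yaml --out dataset.json
segrater evaluate --dataset dataset.json --out eval/
segrater report --dataset dataset.json --metrics eval/metrics.csv --out report/
```

`run` writes the dataset file, `metrics.csv` (one row per annotation),
`table1–3.csv`, `change_summary.csv`, `participant_centroid.csv`, a
heat-map PNG per (group, image, round), a rounded `report.txt`, and a
`manifest.json` that records the full config and library versions — two
runs with the same config and seed are byte-identical.

Datasets are a GeoJSON-dialect FeatureCollection (one Polygon feature per
annotation with `annotator_id` / `image_id` / `round` / `group` properties
and a top-level `frames` member); masks round-trip as single-channel
binary PNGs.

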