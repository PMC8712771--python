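# rssr — seed setting rate from tiled panicle images

`rssr` estimates the **rice seed setting rate** — the fraction of grains on
a panicle that are full (filled) rather than empty — from high-resolution
panicle images processed as a grid of tiles. It is aimed at plant
phenotyping workflows where a detector (a CNN in production, a classical
baseline here) counts grains per tile and the per-image rate must be
reconstructed from those tile-level counts.

Cutting a large image into tiles makes small grains detectable, but it
also cuts grains in two: each grain split by an interior tile boundary
shows up as two `half` boxes. The package implements the corrected
estimator

```
RSSR_t = NF_t / (NF_t + NE_t)                      (traditional, manual counts)

RSSR_a = (NF + PH·NH/2) / (NF + NE + NH/2)         (half-grain corrected)
```

where `NF`, `NE`, `NH` are the detected full, empty and half-box counts
for one image, `NH/2` estimates the number of cut grains, and `PH` is the
prior probability that a cut grain is full, supplied by the linear model

```
PH = 0.797·Ratio1 + 0.1972,   Ratio1 = NF / (NF + NE)      (clamped to [0, 1])
```

The prior can be refit from `(Ratio1, Ratio2)` pairs by ordinary least
squares (`Ratio2 = NFH / (NFH + NEH)` is the full fraction among cut
grains), with a two-sample Kolmogorov–Smirnov check that the two ratio
samples are distributionally consistent.

The package covers the whole bookkeeping chain: box geometry and IOU,
Pascal VOC XML (LabelImg dialect) annotation I/O, grid tiling with
half-grain relabeling (`full`/`empty` → `half` with `H-full`/`H-empty`
provenance), detection evaluation (greedy IOU matching,
precision/recall/F1, non-interpolated AP and mAP, counting-error
statistics, count/rate accuracy), a seeded synthetic darkroom scene
generator with exact ground truth, and a classical threshold-based
baseline detector so everything runs end-to-end without a trained
network. Real detectors plug in through a one-method interface
(`detect(tile_image) -> list[GrainBox]`) or a CSV detection table.

## Worked example

```python
from rssr import SceneConfig, generate_scene, run_pipeline, ThresholdDetector

cfg = SceneConfig(n_panicles=1, grains_per_panicle=(40, 60), true_rssr=0.85, seed=7)
image, annotation, truth = generate_scene(cfg)
nf = sum(t.NF for t in truth); ne = sum(t.NE for t in truth)
print("true counts:", nf, ne, "true RSSR:", round(nf / (nf + ne), 4))

table = run_pipeline([("demo", image, annotation)], detector=ThresholdDetector())
print(table.round(4).to_string(index=False))
```

prints

```
true counts: 32 9 true RSSR: 0.7805
image_id  NF  NE  NH  ratio1     ph  rssr
    demo  22   7  10  0.7586 0.8018 0.765
```

The scene truly holds 32 full and 9 empty grains (rate 0.7805). After 6×4
tiling, the baseline detector finds 22 whole full grains, 7 whole empty
grains and 10 half boxes (≈5 cut grains); the prior evaluated at
`ratio1 = 0.7586` gives `PH = 0.8018`, and the corrected estimate is
0.765 — within 2% of the true rate despite a third of the grains being
cut or near a boundary.

The same flow is available from the shell:

```
rssr generate --out-dir scenes --n-images 5 --seed 7
rssr tile     --images scenes --out-dir tiles --grid 6x4
rssr detect   --tiles tiles --out detections.csv
rssr evaluate --detections detections.csv --truth tiles --iou 0.25 --iou 0.5 --iou 0.75 --out eval.csv
rssr rssr     --images scenes --detector baseline --out rates.csv
rssr report   --rssr-table rates.csv --manifest scenes/manifest.csv --out report.csv
```

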