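# stemtrace

Stem-related phenotype extraction for mature soybean plants from detected
stem-node positions.

Breeding programs select soybean material on stem architecture: plant
height, node (pitch) number, internodal lengths, branch number, branching
angle, main-stem length and stem curvature.  Measuring these by hand with
ruler and protractor is slow; when a harvested plant is photographed flat
on a light background, an object detector (any network that emits Pascal
VOC or JSON boxes for the classes `node` and `label`) can localize the
stem nodes and the 1-cm circular scale marker.  `stemtrace` turns those
detections into traits:

1. **Skeleton reconstruction** — a greedy angle-guided directed search
   orders the unordered node set into a main stem plus branch chains.
   A plant is single-stemmed when, for each judged index *i*, the triplet
   angles agree within the error angle α (default 10°):

   `|∠(nᵢ, nᵢ₊₁, nᵢ₊₂) − ∠(nᵢ, nᵢ₊₁, nᵢ₊₃)| < α`

   Otherwise a vertical corridor (endpoint columns ± 30 px) isolates the
   main-stem candidates; the chain grows from the two bottom-most nodes by
   scoring the next three candidates on the continuation angle at the tip,
   with candidates within α of the best competing on distance.  Leftover
   nodes are chained into branches on each side of the corridor and
   returned to the nearest eligible main-stem node.

2. **Phenotypes** — with `labelsize` = pixels/cm from the marker:
   plant height `‖base − top‖ / labelsize`, per-chain node counts and
   internodal lengths, branch count, branching angles against the local
   stem direction, main-stem length `Σ internodes`, stem curvature
   `height / main-stem length ∈ (0, 1]` (1 = erect, a lodging-resistance
   proxy), and branch morphology (convergent < 30° ≤ semi-open ≤ 60° <
   open by mean branching angle).

3. **Cotyledon node** — the height baseline, located from the image:
   Otsu and triangle thresholds are intersected on the dark side and the
   mean foreground column on the bottom row (the cotyledon is tangent to
   the bottom edge by protocol) gives the base point.

4. **Evaluation metrics** — greedy IoU ≥ 0.5 matching,
   precision/recall/F1, non-interpolated AP and mAP, and counting metrics
   (MAE, MSE, RMSE, coefficient of determination, Pearson's r).

5. **Synthetic plants** — a ground-truthed generator (near-straight stems
   whose adjacent-triplet angles average 173.3774°, branches low on the
   stem, scale marker, detector-noise emulation) makes the whole pipeline
   testable without photographs.

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

Simulate one plant and extract its phenotypes from the (noise-free)
detections:

```sh
stemtrace simulate --n 1 --seed 7 --out demo --no-render
stemtrace extract --detections demo/Annotations/plant0000.xml --out demo/report.json
```

`demo/report.json` then contains (abridged):

```
plant_height_cm      = 28.217
vertical_height_cm   = 28.187
main_stem_length_cm  = 28.433
stem_curvature       = 0.9924
node_count_per_chain = [12, 4]
branch_count         = 1
branching_angles_deg = [60.52]
morphology           = "open"
units                = "cm"
```

Read: a 28.2-cm plant (12 main-stem nodes, one 4-node branch), nearly
erect (curvature 0.992 — chord and path almost coincide), with its single
branch departing at 60.5° from the stem, so the mean branching angle puts
it just into the open morphology class.  The scale was calibrated from the
simulated marker at 40 px/cm.  The same command accepts real LabelImg/VOC
annotations or detector JSON; add `--image plant.jpg` to anchor the height
baseline at the cotyledon node and `--figure skel.png` for an overlay plot.

Other entry points:

```sh
stemtrace evaluate --pred preds/ --truth Annotations/ --out metrics.json
stemtrace dataset manifest --plants 325 --extra 223 --out m.csv
stemtrace dataset augment --manifest m.csv --out m4.csv
stemtrace dataset split --manifest m4.csv --seed 0 --out splits.csv
```

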