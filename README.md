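# beastrack

Cell tracking and Ca²⁺-signal extraction for fluorescence recordings of
**moving, contractile tissue** — the setting where classical
register-then-draw-ROIs workflows break down. The motivating system is
Ca²⁺ imaging of enteric neurons: cells overlap optically, blink as they
fire, and are dragged around by muscle contractions, so no pixel
corresponds to the same physical location twice.

Instead of registering the images, `beastrack` tracks every cell with a
**B-spline explicit active contour**: the boundary is an explicit periodic
spline in polar coordinates about a movable pole,

    r(θ) = Σₖ c[k] · β_d(θ/h − k),

evolved by gradient descent on an energy E = E_d + E_r that combines

- a localized region criterion per contour node, maximizing the separation
  of mean intensities inside vs outside a short band along the node normal
  (robust to absolute intensity changes, i.e. to Ca²⁺ transients),
- shape regularization: concave-curvature, area-range and frame-to-frame
  area-stability penalties,
- contour **competition** between neighboring cells: a proximity penalty
  below a distance threshold d_T and an overlap-area penalty w_c·A_overlap,
  so contours share borderless interfaces instead of invading each other.

Two tracking modes are provided. **One-layer** contours follow the
cytoplasm–background interface. **Double contours** add a coupled inner
contour on the nucleus–cytoplasm interface: GCaMP is excluded from the
nucleus, so every cell carries a dark nucleus whose sharp, stable rim
anchors the cell even when its outer borders are invisible, and signal is
then extracted from cytoplasm pixels only. Tracked centroids can further
serve as landmarks to fit per-frame geometric transforms (translation /
affine / quadratic) and carry manually drawn ROIs through the recording.

A fully ground-truthed synthetic scene generator reproduces the hard parts
of such recordings — overlapping cells with equal baselines and no visible
borders, dark nuclei, per-cell Ca²⁺ transients, contraction-like coherent
motion, out-of-focus frames, sensor noise — and scores tracking (IoU
against true masks) and signal fidelity (normalized RMSE against the true
cytoplasm-mean waveforms).

## Worked example

Simulate a 5-cell, 40-frame scene, track it with double contours, and
score the result:

```sh
cat > run.yaml <<'YAML'
scene:
  n_frames: 40
  n_cells: 5
  image_size: [224, 224]
  seed: 7
tracking:
  mode: double
YAML

beastrack simulate --config run.yaml --out sim/
beastrack track --stack sim/stack.tif --init sim/ellipses.csv --config run.yaml --out run/
beastrack evaluate --traces run/traces.csv --truth sim/truth_waveforms.csv \
                   --masks sim/truth_masks.npz --contours run/contours.csv --out eval.json
```

which prints

```
wrote 40-frame scene with 5 cells to sim
tracked 5 cells over 40 frames (0 non-tracked cell-frames)
{"mean_nrmse": 0.127, "median_nrmse": 0.119,
 "per_cell_iou": {"0": 0.598, "1": 0.787, "2": 0.751, "3": 0.738, "4": 0.831},
 "mean_iou": 0.741}
```

Reading the numbers: every cell stayed tracked through all 40 frames; the
tracked contours overlap the true cell masks with a mean IoU of 0.74; and
the extracted cytoplasm traces deviate from the planted Ca²⁺ waveforms by
a normalized RMSE of 0.09–0.17 per cell (RMSE divided by the waveform's
dynamic range — ~0.1 means the transient shape is recovered with ~10%
error).

The same pipeline is available as library calls
(`beastrack.generate_scene`, `beastrack.track`,
`beastrack.extract_signals`, …); `beastrack roi-track` propagates manual
ROIs (CSV polygons) via landmark transforms fitted from `tracks.json`.
Every run writes a `provenance.json` (tool version, seed, config hash);
identical config and seed reproduce stacks, contours and traces
byte-for-byte.

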