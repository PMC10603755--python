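# Methods

This note records the models, the synthetic study conditions, the
numerical choices and the limits of what the desk-scale experiments
show. Everything quantitative stated here is computed by the test suite
or `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Detector

The backbone (ShallowSE) is five stages of
`conv3×3 → per-pixel layer norm → GeLU → SE`, strides (1, 2, 2, 2, 2),
default widths (16, 32, 64, 128, 256), ending at a single
medium-resolution map of total stride 16. Design points:

- **Per-pixel layer norm everywhere.** Each spatial position's channel
  vector is normalized to zero mean / unit variance (ε = 1e-6, ConvNeXt
  convention) with a per-channel affine. No batch normalization exists
  anywhere in the network, so statistics are independent of batch
  composition.
- **GeLU** is the exact `x·Φ(x)` with the standard-normal CDF (erf
  form), not the tanh approximation; the backward pass uses
  `Φ(x) + x·φ(x)`.
- **SE blocks** use a bias-free two-layer bottleneck with reduction
  r = 4. r is configurable; 4 is the default because the shallow
  stages are narrow (r = 16 would leave fewer than one hidden unit at
  16 channels).
- **Neck/head.** One extra stride-2 context stage is computed from the
  medium map, upsampled (nearest, ×2) and concatenated back, then a
  3-convolution block (1×1, 3×3, 1×1) replaces the classical 5-conv
  PANet block, and a single head (3×3 conv + 1×1 projection) emits
  `A·(5+C)` channels per cell. The unstreamlined reference used for
  parameter comparisons keeps 5-conv blocks and three scale heads; it
  exists only as countable layer descriptors, never as a trained model.
- **Decode/NMS conventions.** Boxes are 0-based, x right / y down,
  half-open `[xmin, xmax)`; centers are `(cell + σ(t))·stride`, sizes
  `anchor·exp(t)` with `t` clipped to ±8 before exponentiation;
  confidence is `σ(obj)·σ(class)`. NMS is greedy by descending
  confidence, suppressing same-class boxes with IoU strictly above the
  threshold (0.45 default). Evaluation uses confidence 0.05, deployment
  0.5.
- **Loss.** CIoU on assigned anchors (weight 5) + binary cross-entropy
  objectness (positives and negatives normalized separately, so sparse
  positives are not drowned) + BCE class. Targets are assigned to the
  cell containing the box center and the best shape-IoU anchor, ties to
  the lowest anchor index; when two targets collide on a slot the
  second takes its next-best free anchor. Zero-area targets are skipped
  with a warning.
- **Anchors** come from IoU-distance k-means (k = 3, seeded Lloyd
  iterations) on the training annotations, with quantile fallbacks when
  boxes are scarce.

### Why numpy, and gradient policy

The whole network stack (conv via im2col, layer norm, GeLU, SE, linear,
Adam) is implemented directly in numpy with hand-written backward
passes; every layer's gradient is checked against central finite
differences in `tests/test_layers.py`, including one end-to-end check
through the full detector. The CIoU term's gradient with respect to the
decoded `(cx, cy, w, h)` is itself taken by central differences (4
scalars per assigned anchor, step 1e-3 of the coordinate scale) and
chained analytically through the sigmoid/exponential decode; with at
most a dozen targets per frame this costs a negligible fraction of the
forward pass and avoids hand-deriving the piecewise IoU/enclosing-box
terms. The full loss gradient (analytic + embedded differences) is
verified against finite differences of the scalar loss.

## Coordinate regression

SmallerFC/SmallFC/BigFC are 2/3/4 fully connected layers (counting the
output layer) with ReLU hidden activations and default hidden widths
(64), (64, 64) and (128, 128, 64) — the widths are free parameters of
the three depth variants and are configurable. Inputs (7) and targets
(2) are z-scored; constant features get a floored σ = 1e-12 with a
warning. Training is full-batch Adam on scaled MSE, one gradient step
per epoch, Kaiming-uniform seeded initialization. The signature
defaults (20 000 epochs, lr 1e-4) mirror the original field protocol;
all desk-scale runs in this repository use 1500–4000 epochs, which
suffices on synthetic data and keeps the suite inside a few CPU
minutes. Records with missing `Xw`/`Zw` are dropped (counted) before
training; a forward-fill-by-Num alternative exists because field logs
repeat positions across adjacent frames. Train/test splits are made
over contiguous Num blocks, not records, because consecutive frames are
nearly identical and a random split would leak.

Error statistics are Euclidean distances in the (Xw, Zw) ground plane
(mean and max). Per-axis errors are east-west and north-south ground
distances after the local equirectangular conversion
`Δlat = zw/111320`, `Δlon = xw/(111320·cos lat)`.

## Synthetic study conditions

The simulator fixes the acquisition geometry the method assumes: camera
base at the world origin, Xw east / Zw north / Yw up, mast height
15.6 m, pan clockwise from north, tilt positive downward, zoom dividing
a 60° base horizontal field of view. The flock is 11 animals on a
correlated random walk (AR(1) velocity, autocorrelation 0.7, stationary
per-axis step σ = 0.15 m/frame near-field, plus a centroid-cohesion
pull scaled by the step σ so a zero-σ flock is exactly stationary).
Animals are 1.2 m long, 0.8 m tall boxes; their 8 corners project
through the pinhole model to the annotation envelope.

Two scenario presets define the experiments:

- **near-field** (detector fixtures, end-to-end runs): flock ~40–80 m
  out, zoom 6–9, 96 px frames, so one animal spans roughly 8–15 px.
- **far-field** (coordinate-table emulation): flock ~250–400 m at
  bearing ~146°, tilt a few degrees, zoom 3.8–18.4, 416 px frames —
  pose magnitudes and negative hundreds-of-meters world coordinates
  shaped like published field logs. The synthetic frame is
  self-consistent but makes no claim to match any particular field
  site's (unstated) datum.

Coordinate records add Gaussian GPS noise (σ = 1.5 m default, the rated
accuracy class of livestock GPS locators), 1 px Gaussian jitter on box
edges to mimic detector noise, and a 5% per-coordinate missingness rate
written as `--` in the CSV.

What the simulator does **not** model: occlusion between animals beyond
painter's-order rendering, terrain elevation, lens distortion, lighting
and weather variation, animal posture, or herding around obstacles.
Passing tests therefore demonstrate that the architecture and the
geometry pipeline are implemented correctly and that the method is
learnable when its assumptions hold — not field accuracy on real
pastures.

## Desk-scale experiment sizes

Chosen as the package's own working points so a laptop CPU reproduces
everything in minutes:

- Detector fixture: 50 rendered 96 px frames, stage widths
  (8, 16, 32, 48, 64), batch 16, lr 1e-3, 100 epochs. The fixed-seed
  fixture reaches AP@0.5 ≈ 0.87 on its training set; seed-to-seed
  spread of roughly ±0.1 AP is normal at this tiny scale.
- Regressor comparison: 5000-record far-field table (GPS noise and
  missingness on), equal budgets of 2000 epochs at lr 1e-4 per variant.
  Average training error orders BigFC ≤ SmallFC ≤ SmallerFC — the
  capacity trend the three depths exist to show. An overfitting probe
  (held-out spatial blocks) is reported but its ordering is not
  asserted: at this scale it is seed-dependent.
- End-to-end: BigFC trained on noiseless near-field records (400
  frames), fixture detector, 12 held-out frames; detections are matched
  to true positions by nearest neighbor with a 5 m gate. Average
  ground-plane error lands well under 2 m (≈1.2–1.5 m depending on
  seed), the desk-scale analogue of sub-meter field claims.

## Degenerate inputs and numeric guards

Empty feature maps, non-finite activations, zero-area boxes, empty
anchor lists, mismatched list lengths and pole-adjacent geo origins all
raise; decode clamps `exp` arguments; AP with zero ground truth is an
error (undefined), while AP with zero detections is 0. MAC accounting
counts one multiply-accumulate as one operation and excludes biases and
normalization, so reported complexity matches how detector tables are
conventionally printed; parameter counting is closed-form per layer and
is cross-checked against enumeration of the actual weight arrays for
every model built in the repo.

## Known limitations

- The detector trains only at fixture scale here; no claim is made
  about mAP on real imagery, and multi-scale heads were deliberately
  not implemented (the streamlining is the point).
- The published parameter totals for the three backbone families are
  recomputed as arithmetic (reduction percentages), not rebuilt as
  models; only the ShallowSE-family architecture itself is
  instantiated.
- Full-batch regression training is O(n) per epoch in records; beyond
  ~10⁵ records mini-batching would be needed.
- The equirectangular geo conversion is valid for the few-kilometer
  extents of a pasture, not for continental distances.
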