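"""Shallow SE-attention single-scale detector (ShallowSE + Custom_YOLO).

The backbone is a stack of [conv -> per-pixel layer norm -> GeLU -> SE]
stages with stride-2 downsampling to a single medium-resolution feature
map (total stride 16); batch normalization appears nowhere.  The neck
fuses one deeper context level back into the medium map and processes it
with a 3-convolution block (the streamlined replacement for a 5-conv
PANet block), and a single YOLO-style head predicts
``A * (5 + num_classes)`` channels per cell.  Training uses CIoU box
loss plus binary cross-entropy objectness/class terms and Adam.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .counting import LayerSpec, count_parameters
from .layers import (GELU, Adam, Conv2d, Layer, NearestUpsample2x, Param,
                     PixelLayerNorm, SEBlock, Sequential, n_params)

__all__ = [
    "DetectorConfig",
    "Detection",
    "GroundTruthBox",
    "RawHeadOutput",
    "ShallowSE",
    "CustomYOLO",
    "build_shallowse",
    "build_custom_yolo",
    "custom_yolo_layer_specs",
    "decode_predictions",
    "nms",
    "detection_loss",
    "train_detector",
    "kmeans_anchors",
    "DEFAULT_ANCHORS",
]

STRIDE = 16

# fallback medium-scale priors (px) for a 416-px frame; real runs fit
# anchors to the training annotations with kmeans_anchors
DEFAULT_ANCHORS = ((30.0, 20.0), (60.0, 40.0), (110.0, 75.0))


@dataclass(frozen=True)
class DetectorConfig:
    input_size: int = 416
    in_channels: int = 3
    stage_channels: tuple = (16, 32, 64, 128, 256)
    se_reduction: int = 4
    anchors: tuple = DEFAULT_ANCHORS
    num_classes: int = 1
    conf_threshold: float = 0.05
    nms_iou_threshold: float = 0.45

    def __post_init__(self):
        if self.input_size % STRIDE != 0 or self.input_size <= 0:
            raise ValueError(f"input_size must be a positive multiple of {STRIDE}")
        if len(self.anchors) < 1:
            raise ValueError("at least one anchor is required")
        if not (0.0 <= self.conf_threshold <= 1.0 and 0.0 <= self.nms_iou_threshold <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if len(self.stage_channels) != 5:
            raise ValueError("expected 5 backbone stage widths")

    @property
    def grid_size(self) -> int:
        return self.input_size // STRIDE

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def head_channels(self) -> int:
        return self.n_anchors * (5 + self.num_classes)


@dataclass
class Detection:
    """Pixel-space box, 0-based, x right / y down, half-open edges."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    confidence: float
    class_id: int = 0

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("degenerate detection box")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def box(self):
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass
class GroundTruthBox:
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    class_id: int = 0

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("degenerate ground-truth box")

    @property
    def box(self):
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass
class RawHeadOutput:
    """Undecoded head activations for one image, (Hg, Wg, A*(5+nc))."""

    grid: np.ndarray
    stride: int = STRIDE


class ShallowSE(Layer):
    """Backbone: five [conv-LN-GeLU-SE] stages, strides (1, 2, 2, 2, 2)."""

    def __init__(self, cfg: DetectorConfig, rng=None):
        rng = np.random.default_rng(rng)
        chans = cfg.stage_channels
        stages = []
        cin = cfg.in_channels
        for i, cout in enumerate(chans):
            stride = 1 if i == 0 else 2
            stages.append(Sequential(
                Conv2d(cin, cout, kernel=3, stride=stride, bias=False, rng=rng),
                PixelLayerNorm(cout),
                GELU(),
                SEBlock(cout, reduction=cfg.se_reduction, rng=rng),
            ))
            cin = cout
        self.stages = stages
        self.cfg = cfg

    def params(self):
        return [p for s in self.stages for p in s.params()]

    def layer_specs(self):
        return [sp for s in self.stages for sp in s.layer_specs()]

    def forward(self, x):
        for s in self.stages:
            x = s.forward(x)
        return x

    def backward(self, dy):
        for s in reversed(self.stages):
            dy = s.backward(dy)
        return dy

    def n_parameters(self) -> int:
        return count_parameters(self.layer_specs())


class CustomYOLO(Layer):
    """Backbone + deep-context fusion + 3-conv neck + single medium head."""

    NECK_CONV_COUNT = 3

    def __init__(self, cfg: DetectorConfig, rng=None):
        rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.backbone = ShallowSE(cfg, rng=rng)
        c = cfg.stage_channels[-1]
        self.deep = Sequential(
            Conv2d(c, c, kernel=3, stride=2, bias=False, rng=rng),
            PixelLayerNorm(c), GELU(),
        )
        self.up = NearestUpsample2x()
        # streamlined PANet block: 3 convolutions instead of 5
        self.neck = Sequential(
            Conv2d(2 * c, c, kernel=1, bias=False, rng=rng), PixelLayerNorm(c), GELU(),
            Conv2d(c, c, kernel=3, bias=False, rng=rng), PixelLayerNorm(c), GELU(),
            Conv2d(c, c // 2, kernel=1, bias=False, rng=rng), PixelLayerNorm(c // 2), GELU(),
        )
        self.head = Sequential(
            Conv2d(c // 2, c, kernel=3, bias=False, rng=rng), PixelLayerNorm(c), GELU(),
            Conv2d(c, cfg.head_channels, kernel=1, bias=True, rng=rng),
        )
        self._cache = None

    @property
    def neck_depth(self) -> int:
        return self.NECK_CONV_COUNT

    def params(self):
        return (self.backbone.params() + self.deep.params()
                + self.neck.params() + self.head.params())

    def layer_specs(self):
        return (self.backbone.layer_specs() + self.deep.layer_specs()
                + self.neck.layer_specs() + self.head.layer_specs())

    def forward(self, x):
        m = self.backbone.forward(x)  # medium map, stride 16
        d = self.deep.forward(m)  # stride 32 context
        u = self.up.forward(d)
        u_shape = u.shape
        u = u[:, :, :m.shape[2], :m.shape[3]]  # crop for odd medium grids
        fused = np.concatenate([m, u], axis=1)
        y = self.head.forward(self.neck.forward(fused))
        self._cache = (m.shape[1], u_shape)
        return y

    def backward(self, dy):
        c_m, u_shape = self._cache
        dfused = self.neck.backward(self.head.backward(dy))
        dm = dfused[:, :c_m]
        du_crop = dfused[:, c_m:]
        du = np.zeros(u_shape, dtype=dy.dtype)
        du[:, :, :du_crop.shape[2], :du_crop.shape[3]] = du_crop
        dm = dm + self.deep.backward(self.up.backward(du))
        return self.backbone.backward(dm)

    def n_parameters(self) -> int:
        return count_parameters(self.layer_specs())

    def predict_raw(self, images: np.ndarray) -> list[RawHeadOutput]:
        """Forward a (N, C, H, W) batch into per-image head grids."""
        y = self.forward(images)
        return [RawHeadOutput(grid=np.transpose(g, (1, 2, 0)), stride=STRIDE)
                for g in y]

    def detect(self, image_chw: np.ndarray, conf_threshold=None) -> list[Detection]:
        """Decode + NMS for one (C, H, W) image."""
        raw = self.predict_raw(image_chw[None])[0]
        dets = decode_predictions(raw, self.cfg, conf_threshold=conf_threshold)
        return nms(dets, self.cfg.nms_iou_threshold)


def build_shallowse(cfg: DetectorConfig = DetectorConfig(), rng=None) -> ShallowSE:
    return ShallowSE(cfg, rng=rng)


def build_custom_yolo(cfg: DetectorConfig = DetectorConfig(), rng=None) -> CustomYOLO:
    return CustomYOLO(cfg, rng=rng)


def custom_yolo_layer_specs(cfg: DetectorConfig, streamlined: bool = True):
    """Countable layer descriptors for the streamlined model or the
    unstreamlined reference (5-conv PANet blocks and three scale heads).

    The reference variant is never trained here; it exists so that the
    parameter reduction from streamlining can be computed for any
    backbone width configuration.
    """
    if streamlined:
        return CustomYOLO(cfg).layer_specs()
    specs = list(ShallowSE(cfg).layer_specs())
    c = cfg.stage_channels[-1]
    # three pyramid levels, each with a 5-convolution block and its own head
    for level_c in (cfg.stage_channels[-3], cfg.stage_channels[-2], c):
        cin = 2 * level_c  # fused input at that level
        widths = (level_c, 2 * level_c, level_c, 2 * level_c, level_c)
        kernels = (1, 3, 1, 3, 1)
        for w, k in zip(widths, kernels):
            specs.append(LayerSpec("conv", cin=cin, cout=w, kernel=k, bias=False))
            specs.append(LayerSpec("norm", channels=w))
            cin = w
        specs.append(LayerSpec("conv", cin=cin, cout=2 * level_c, kernel=3, bias=False))
        specs.append(LayerSpec("norm", channels=2 * level_c))
        specs.append(LayerSpec("conv", cin=2 * level_c, cout=cfg.head_channels,
                               kernel=1, bias=True))
    return specs


def _sigmoid(x):
    return expit(x)


def decode_predictions(raw: RawHeadOutput, cfg: DetectorConfig,
                       conf_threshold: float | None = None) -> list[Detection]:
    """Decode a head grid into pixel-space detections.

    Per cell (i, j) and anchor a: center = (cell + sigmoid(txy)) * stride,
    size = anchor * exp(twh), confidence = sigmoid(obj) * sigmoid(class).
    Boxes are clipped to the frame; only boxes at or above the confidence
    threshold survive.
    """
    thr = cfg.conf_threshold if conf_threshold is None else conf_threshold
    g = np.asarray(raw.grid, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite values in raw head output")
    hg, wg, _ = g.shape
    a = cfg.n_anchors
    g = g.reshape(hg, wg, a, 5 + cfg.num_classes)
    jj, ii = np.meshgrid(np.arange(wg), np.arange(hg))
    anchors = np.asarray(cfg.anchors, dtype=float)
    cx = (jj[..., None] + _sigmoid(g[..., 0])) * raw.stride
    cy = (ii[..., None] + _sigmoid(g[..., 1])) * raw.stride
    w = anchors[None, None, :, 0] * np.exp(np.clip(g[..., 2], -8.0, 8.0))
    h = anchors[None, None, :, 1] * np.exp(np.clip(g[..., 3], -8.0, 8.0))
    obj = _sigmoid(g[..., 4])
    cls = _sigmoid(g[..., 5:])
    class_id = np.argmax(cls, axis=-1)
    conf = obj * np.take_along_axis(cls, class_id[..., None], axis=-1)[..., 0]
    size = float(cfg.input_size)
    dets = []
    keep = np.argwhere(conf >= thr)
    for i, j, k in keep:
        xmin = max(cx[i, j, k] - w[i, j, k] / 2.0, 0.0)
        ymin = max(cy[i, j, k] - h[i, j, k] / 2.0, 0.0)
        xmax = min(cx[i, j, k] + w[i, j, k] / 2.0, size)
        ymax = min(cy[i, j, k] + h[i, j, k] / 2.0, size)
        if xmin >= xmax or ymin >= ymax:
            continue
        dets.append(Detection(xmin, ymin, xmax, ymax,
                              confidence=float(conf[i, j, k]),
                              class_id=int(class_id[i, j, k])))
    dets.sort(key=lambda d: -d.confidence)
    return dets


def _box_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def nms(dets: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression, descending confidence.

    A box is dropped when its IoU with an already kept box of the same
    class strictly exceeds the threshold.  Output stays sorted by
    confidence.
    """
    order = sorted(dets, key=lambda d: -d.confidence)
    kept: list[Detection] = []
    for d in order:
        if all(k.class_id != d.class_id or _box_iou(d.box, k.box) <= iou_threshold
               for k in kept):
            kept.append(d)
    return kept


def _ciou(pred, tgt) -> float:
    """Complete IoU between two (cx, cy, w, h) boxes."""
    px1, py1 = pred[0] - pred[2] / 2, pred[1] - pred[3] / 2
    px2, py2 = pred[0] + pred[2] / 2, pred[1] + pred[3] / 2
    tx1, ty1 = tgt[0] - tgt[2] / 2, tgt[1] - tgt[3] / 2
    tx2, ty2 = tgt[0] + tgt[2] / 2, tgt[1] + tgt[3] / 2
    iou = _box_iou((px1, py1, px2, py2), (tx1, ty1, tx2, ty2))
    cw = max(px2, tx2) - min(px1, tx1)
    ch = max(py2, ty2) - min(py1, ty1)
    c2 = cw * cw + ch * ch + 1e-9
    rho2 = (pred[0] - tgt[0]) ** 2 + (pred[1] - tgt[1]) ** 2
    v = (4.0 / math.pi ** 2) * (math.atan(tgt[2] / max(tgt[3], 1e-9))
                                - math.atan(pred[2] / max(pred[3], 1e-9))) ** 2
    alpha = v / (1.0 - iou + v + 1e-9)
    return iou - rho2 / c2 - alpha * v


def _anchor_shape_iou(anchor, wh) -> float:
    iw = min(anchor[0], wh[0])
    ih = min(anchor[1], wh[1])
    inter = iw * ih
    union = anchor[0] * anchor[1] + wh[0] * wh[1] - inter
    return inter / union if union > 0 else 0.0


def _assign_targets(targets, cfg: DetectorConfig):
    """Map each target to (cell_i, cell_j, anchor); best shape-IoU anchor,
    ties to the lowest index, falling back to the next-best free anchor
    when two targets land on the same slot."""
    gs = cfg.grid_size
    taken = set()
    assignments = []
    for t in targets:
        w, h = t.xmax - t.xmin, t.ymax - t.ymin
        if w <= 0 or h <= 0:
            warnings.warn("skipping degenerate zero-area target box")
            continue
        cx, cy = (t.xmin + t.xmax) / 2.0, (t.ymin + t.ymax) / 2.0
        j = min(int(cx // STRIDE), gs - 1)
        i = min(int(cy // STRIDE), gs - 1)
        ious = [_anchor_shape_iou(a, (w, h)) for a in cfg.anchors]
        for a_idx in sorted(range(len(ious)), key=lambda k: (-ious[k], k)):
            if (i, j, a_idx) not in taken:
                taken.add((i, j, a_idx))
                assignments.append((i, j, a_idx, t, (cx, cy, w, h)))
                break
    return assignments


def _bce(p, y):
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def detection_loss(raw, targets, cfg: DetectorConfig, *, box_weight: float = 5.0,
                   return_grad: bool = False):
    """CIoU + BCE objectness + BCE class loss for one image.

    ``raw`` is a RawHeadOutput or an (Hg, Wg, A*(5+nc)) array.  The box
    term averages (1 - CIoU) over assigned anchors; objectness balances
    positive and negative cells; the class term is BCE at positives.
    With ``return_grad`` the gradient w.r.t. the raw grid is returned as
    well (analytic for the BCE terms, central finite differences through
    CIoU w.r.t. the decoded box, chained through the decode transform).
    """
    grid = raw.grid if isinstance(raw, RawHeadOutput) else raw
    grid = np.asarray(grid, dtype=float)
    hg, wg, _ = grid.shape
    a = cfg.n_anchors
    nc = cfg.num_classes
    g = grid.reshape(hg, wg, a, 5 + nc)
    grad = np.zeros_like(g)
    assignments = _assign_targets(targets, cfg)
    anchors = np.asarray(cfg.anchors, dtype=float)

    obj_target = np.zeros((hg, wg, a))
    for i, j, k, t, _ in assignments:
        obj_target[i, j, k] = 1.0

    obj_p = _sigmoid(g[..., 4])
    pos_mask = obj_target > 0
    n_pos = max(int(pos_mask.sum()), 1)
    n_cells = obj_target.size
    bce_all = _bce(obj_p, obj_target)
    obj_loss = bce_all[~pos_mask].sum() / n_cells + bce_all[pos_mask].sum() / n_pos
    dobj = (obj_p - obj_target)
    dobj = np.where(pos_mask, dobj / n_pos, dobj / n_cells)
    grad[..., 4] = dobj

    box_loss = 0.0
    cls_loss = 0.0
    n_assigned = max(len(assignments), 1)
    for i, j, k, t, (cx, cy, w, h) in assignments:
        tx, ty, tw, th = g[i, j, k, :4]
        sx, sy = _sigmoid(tx), _sigmoid(ty)
        pw = anchors[k, 0] * math.exp(float(np.clip(tw, -8, 8)))
        ph = anchors[k, 1] * math.exp(float(np.clip(th, -8, 8)))
        pcx = (j + sx) * STRIDE
        pcy = (i + sy) * STRIDE
        pred = np.array([pcx, pcy, pw, ph])
        tgt = (cx, cy, w, h)
        box_loss += 1.0 - _ciou(pred, tgt)
        if return_grad:
            d = np.zeros(4)
            for q in range(4):
                step = 1e-3 * max(abs(pred[q]), 1.0)
                hi = pred.copy(); hi[q] += step
                lo = pred.copy(); lo[q] -= step
                d[q] = (_ciou(lo, tgt) - _ciou(hi, tgt)) / (2 * step)  # d(1-ciou)/dq
            scale = box_weight / n_assigned
            grad[i, j, k, 0] += scale * d[0] * sx * (1 - sx) * STRIDE
            grad[i, j, k, 1] += scale * d[1] * sy * (1 - sy) * STRIDE
            grad[i, j, k, 2] += scale * d[2] * pw
            grad[i, j, k, 3] += scale * d[3] * ph
        cls_p = _sigmoid(g[i, j, k, 5:])
        onehot = np.zeros(nc)
        onehot[t.class_id] = 1.0
        cls_loss += _bce(cls_p, onehot).sum()
        grad[i, j, k, 5:] = (cls_p - onehot) / n_assigned
    box_loss /= n_assigned
    cls_loss /= n_assigned
    loss = box_weight * box_loss + obj_loss + cls_loss
    if return_grad:
        return float(loss), grad.reshape(hg, wg, a * (5 + nc))
    return float(loss)


def kmeans_anchors(boxes_wh, k: int = 3, seed: int = 0, n_iter: int = 50):
    """IoU-distance k-means over annotation (w, h) pairs; returns k priors
    sorted by area.  Falls back to quantiles when there are too few boxes."""
    wh = np.asarray(boxes_wh, dtype=float)
    if len(wh) < k:
        scale = wh.mean(axis=0) if len(wh) else np.array([30.0, 20.0])
        return tuple((float(scale[0] * f), float(scale[1] * f))
                     for f in np.linspace(0.7, 1.4, k))
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), size=k, replace=False)]
    for _ in range(n_iter):
        d = np.empty((len(wh), k))
        for c in range(k):
            iw = np.minimum(wh[:, 0], centers[c, 0])
            ih = np.minimum(wh[:, 1], centers[c, 1])
            inter = iw * ih
            union = wh[:, 0] * wh[:, 1] + centers[c].prod() - inter
            d[:, c] = 1.0 - inter / np.maximum(union, 1e-12)
        lab = d.argmin(axis=1)
        new = centers.copy()
        for c in range(k):
            if np.any(lab == c):
                new[c] = wh[lab == c].mean(axis=0)
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers.prod(axis=1))
    return tuple((float(w), float(h)) for w, h in centers[order])


def train_detector(dataset, cfg: DetectorConfig, *, epochs: int = 100,
                   lr: float = 1e-3, batch_size: int = 16, seed: int = 0,
                   model: CustomYOLO | None = None):
    """Train a CustomYOLO on (image, boxes) pairs.

    ``dataset`` is a sequence of ``(image, boxes)`` with images either
    (H, W, 3) or (3, H, W) float arrays in [0, 1] and boxes lists of
    GroundTruthBox.  Full-dataset epochs with shuffled mini-batches of
    ``batch_size`` (16 by default) and Adam at ``lr`` (1e-3 by default).
    Returns (model, per-epoch mean loss history); deterministic given
    the seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    images = []
    for img, _ in dataset:
        arr = np.asarray(img, dtype=np.float32)
        if arr.ndim == 3 and arr.shape[2] in (1, 3):
            arr = np.transpose(arr, (2, 0, 1))
        images.append(arr)
    images = np.stack(images)
    boxes = [b for _, b in dataset]
    if model is None:
        model = CustomYOLO(cfg, rng=np.random.default_rng(seed + 1))
    opt = Adam(model.params(), lr=lr)
    history = []
    n = len(dataset)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = images[idx]
            raw = model.forward(batch)  # (B, C, Hg, Wg)
            grads = np.zeros_like(raw)
            for bi, di in enumerate(idx):
                grid = np.transpose(raw[bi], (1, 2, 0))
                loss, grad = detection_loss(grid, boxes[di], cfg, return_grad=True)
                epoch_loss += loss
                grads[bi] = np.transpose(grad, (2, 0, 1))
            if lr > 0:
                opt.zero_grad()
                model.backward(grads.astype(raw.dtype) / len(idx))
                opt.step()
        history.append(epoch_loss / n)
    return model, history
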