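"""Fully connected coordinate regression: image box + PTZ pose -> world.

Three capacity variants map the 7 inputs (xmin, ymin, xmax, ymax, pan,
tilt, zoom) to the ground-plane world coordinates (Xw, Zw) in meters:

* SmallerFC — 2 fully connected layers (one hidden block)
* SmallFC   — 3 fully connected layers
* BigFC     — 4 fully connected layers

Hidden layers use ReLU; the output layer is linear.  Inputs and targets
are z-scored before training and predictions are de-scaled back to
meters.  Training minimizes mean squared error with full-batch Adam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .layers import Adam, Linear, ReLU, Sequential, n_params
from .ptz import CoordRecord

__all__ = [
    "RegressorSpec",
    "FeatureScaler",
    "ErrorStats",
    "build_regressor",
    "fit_scaler",
    "complete_records",
    "fill_missing_by_num",
    "split_by_num_blocks",
    "train_regressor",
    "predict_world_coords",
    "predict_batch",
    "error_stats",
]

N_INPUTS = 7
N_OUTPUTS = 2

_VARIANT_DEPTH = {"SmallerFC": 2, "SmallFC": 3, "BigFC": 4}
_DEFAULT_WIDTHS = {
    "SmallerFC": (64,),
    "SmallFC": (64, 64),
    "BigFC": (128, 128, 64),
}


@dataclass(frozen=True)
class RegressorSpec:
    """Depth variant plus hidden widths; depth counts the output layer."""

    variant: str = "BigFC"
    hidden_widths: tuple = None

    def __post_init__(self):
        if self.variant not in _VARIANT_DEPTH:
            raise ValueError(f"unknown variant {self.variant!r}")
        widths = self.hidden_widths
        if widths is None:
            widths = _DEFAULT_WIDTHS[self.variant]
            object.__setattr__(self, "hidden_widths", widths)
        if len(widths) + 1 != _VARIANT_DEPTH[self.variant]:
            raise ValueError(
                f"{self.variant} needs {_VARIANT_DEPTH[self.variant] - 1} hidden "
                f"widths, got {len(widths)}")
        if any(w <= 0 for w in widths):
            raise ValueError("hidden widths must be positive")

    @property
    def n_layers(self) -> int:
        return _VARIANT_DEPTH[self.variant]


def build_regressor(spec: RegressorSpec = RegressorSpec(), seed: int = 0) -> Sequential:
    """Feed-forward 7 -> hidden... -> 2 network for the given variant."""
    rng = np.random.default_rng(seed)
    layers = []
    cin = N_INPUTS
    for w in spec.hidden_widths:
        layers += [Linear(cin, w, rng=rng, dtype=np.float64), ReLU()]
        cin = w
    layers.append(Linear(cin, N_OUTPUTS, rng=rng, dtype=np.float64))
    model = Sequential(*layers)
    model.spec = spec
    model.trained = False
    return model


@dataclass
class FeatureScaler:
    """Per-feature z-score statistics for the 7 inputs and 2 targets."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    def apply_x(self, x):
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_std

    def apply_y(self, y):
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def invert_y(self, y):
        return np.asarray(y, dtype=float) * self.y_std + self.y_mean

    def invert_x(self, x):
        return np.asarray(x, dtype=float) * self.x_std + self.x_mean


def _design_matrices(records):
    recs = [r for r in records if r.complete]
    x = np.stack([r.inputs() for r in recs]) if recs else np.empty((0, N_INPUTS))
    y = np.stack([r.targets() for r in recs]) if recs else np.empty((0, N_OUTPUTS))
    return x, y


def fit_scaler(records) -> FeatureScaler:
    """Z-score statistics from complete records; constant features keep a
    floored std so scaling stays invertible."""
    x, y = _design_matrices(records)
    if len(x) < 2:
        raise ValueError("need at least 2 complete records to fit a scaler")

    def _std(a):
        s = a.std(axis=0)
        if np.any(s < 1e-12):
            warnings.warn("constant feature: std floored at 1e-12")
            s = np.maximum(s, 1e-12)
        return s

    return FeatureScaler(x_mean=x.mean(axis=0), x_std=_std(x),
                         y_mean=y.mean(axis=0), y_std=_std(y))


def complete_records(records):
    """Drop records with missing world coordinates; returns (kept, n_dropped)."""
    kept = [r for r in records if r.complete]
    return kept, len(records) - len(kept)


def fill_missing_by_num(records):
    """Forward-fill missing Xw/Zw from the nearest earlier record, in Num
    order (field logs repeat positions across adjacent frames)."""
    out = []
    last_x = last_z = None
    for r in sorted(records, key=lambda r: r.num):
        xw = r.xw if r.xw is not None else last_x
        zw = r.zw if r.zw is not None else last_z
        if r.xw is not None:
            last_x = r.xw
        if r.zw is not None:
            last_z = r.zw
        out.append(CoordRecord(num=r.num, xmin=r.xmin, ymin=r.ymin, xmax=r.xmax,
                               ymax=r.ymax, pan=r.pan, tilt=r.tilt, zoom=r.zoom,
                               xw=xw, zw=zw))
    return out


def split_by_num_blocks(records, test_fraction: float = 0.2, n_blocks: int = 10,
                        seed: int = 0):
    """80/20-style split over contiguous Num blocks.

    Random record-level splits leak because consecutive frames are nearly
    identical; instead the Num-ordered sequence is cut into ``n_blocks``
    contiguous chunks and whole chunks are drawn for the test side.
    """
    recs = sorted(records, key=lambda r: r.num)
    rng = np.random.default_rng(seed)
    bounds = np.linspace(0, len(recs), n_blocks + 1).astype(int)
    n_test = max(int(round(test_fraction * n_blocks)), 1)
    test_blocks = set(rng.choice(n_blocks, size=n_test, replace=False).tolist())
    train, test = [], []
    for b in range(n_blocks):
        chunk = recs[bounds[b]:bounds[b + 1]]
        (test if b in test_blocks else train).extend(chunk)
    return train, test


def train_regressor(model, records, epochs: int = 20000, lr: float = 1e-4,
                    seed: int = 0, scaler: FeatureScaler | None = None):
    """Fit the regressor with full-batch Adam on z-scored MSE.

    Records with missing targets must be excluded (or filled) upstream.
    Returns ``(model, scaler, loss_history)``; the history has one scaled
    MSE entry per epoch and the run is deterministic given the seed.
    The 20000-epoch / lr=1e-4 defaults follow the study protocol;
    desk-scale runs in this repo use a few thousand epochs.
    """
    x, y = _design_matrices(records)
    if len(x) == 0:
        raise ValueError("no complete records to train on")
    if scaler is None:
        scaler = fit_scaler(records)
    xs = scaler.apply_x(x)
    ys = scaler.apply_y(y)
    opt = Adam(model.params(), lr=lr)
    history = np.empty(epochs)
    n = len(xs)
    for e in range(epochs):
        pred = model.forward(xs)
        resid = pred - ys
        history[e] = float((resid ** 2).mean())
        if lr > 0:
            opt.zero_grad()
            model.backward(2.0 * resid / resid.size)
            opt.step()
    model.trained = True
    return model, scaler, history


def predict_batch(model, scaler: FeatureScaler, records) -> np.ndarray:
    """De-scaled (Xw, Zw) predictions in meters, shape (n, 2)."""
    if not getattr(model, "trained", False):
        raise ValueError("model has not been trained")
    x = np.stack([r.inputs() for r in records])
    return scaler.invert_y(model.forward(scaler.apply_x(x)))


def predict_world_coords(model, scaler: FeatureScaler, record) -> tuple:
    """World-coordinate prediction for a single record."""
    xw, zw = predict_batch(model, scaler, [record])[0]
    return float(xw), float(zw)


@dataclass(frozen=True)
class ErrorStats:
    average_error: float  # meters
    maximum_error: float  # meters

    def __post_init__(self):
        if not 0.0 <= self.average_error <= self.maximum_error:
            raise ValueError("require 0 <= average <= maximum")


def error_stats(predictions, truths) -> ErrorStats:
    """Euclidean ground-plane error: mean and max over samples."""
    p = np.asarray(predictions, dtype=float).reshape(-1, 2)
    t = np.asarray(truths, dtype=float).reshape(-1, 2)
    if len(p) != len(t) or len(p) == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    d = np.hypot(p[:, 0] - t[:, 0], p[:, 1] - t[:, 1])
    return ErrorStats(average_error=float(d.mean()), maximum_error=float(d.max()))
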