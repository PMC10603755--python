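"""File formats: coordinate CSV, YOLO-txt annotations, model archives.

Coordinate CSV dialect: header ``Num,xmin,ymin,xmax,ymax,Pan,Tilt,Zoom,Xw,Zw``,
UTF-8, with ``--`` (or an empty field) marking a missing world
coordinate.  YOLO annotations are one ``class cx cy w h`` line per box
with center/size normalized to [0, 1]; pixel boxes are 0-based with
half-open edges.  Trained models ship as a single ``.npz`` archive
bundling the weight arrays with a JSON metadata header (variant or
detector config, scaler statistics).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import CustomYOLO, DetectorConfig, GroundTruthBox
from .ptz import CoordRecord
from .regression import FeatureScaler, RegressorSpec, build_regressor

__all__ = [
    "COORD_CSV_HEADER",
    "read_coord_csv",
    "write_coord_csv",
    "read_yolo_annotations",
    "write_yolo_annotations",
    "save_regressor_archive",
    "load_regressor_archive",
    "save_detector_archive",
    "load_detector_archive",
    "read_yaml",
    "write_yaml",
    "save_png",
    "load_png",
]

COORD_CSV_HEADER = ["Num", "xmin", "ymin", "xmax", "ymax",
                    "Pan", "Tilt", "Zoom", "Xw", "Zw"]
_MISSING = "--"


def read_coord_csv(path) -> list[CoordRecord]:
    """Parse a coordinate-conversion CSV into records.

    ``--`` or empty Xw/Zw fields become None.  Malformed numeric fields
    raise with the offending line number; an unexpected header is a
    format error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != COORD_CSV_HEADER:
        raise ValueError(
            f"unexpected header {list(df.columns)}; expected {COORD_CSV_HEADER}")
    records = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        vals = {}
        for name, raw in zip(COORD_CSV_HEADER, row):
            raw = str(raw).strip()
            if name in ("Xw", "Zw") and raw in (_MISSING, ""):
                vals[name] = None
                continue
            try:
                vals[name] = int(raw) if name == "Num" else float(raw)
            except ValueError as exc:
                raise ValueError(f"line {row_idx}: bad value {raw!r} for {name}") from exc
        records.append(CoordRecord(num=vals["Num"], xmin=vals["xmin"], ymin=vals["ymin"],
                                   xmax=vals["xmax"], ymax=vals["ymax"], pan=vals["Pan"],
                                   tilt=vals["Tilt"], zoom=vals["Zoom"],
                                   xw=vals["Xw"], zw=vals["Zw"]))
    return records


def write_coord_csv(path, records) -> None:
    rows = []
    for r in records:
        rows.append({
            "Num": r.num,
            "xmin": repr(float(r.xmin)), "ymin": repr(float(r.ymin)),
            "xmax": repr(float(r.xmax)), "ymax": repr(float(r.ymax)),
            "Pan": repr(float(r.pan)), "Tilt": repr(float(r.tilt)),
            "Zoom": repr(float(r.zoom)),
            "Xw": _MISSING if r.xw is None else repr(float(r.xw)),
            "Zw": _MISSING if r.zw is None else repr(float(r.zw)),
        })
    pd.DataFrame(rows, columns=COORD_CSV_HEADER).to_csv(path, index=False)


def read_yolo_annotations(path, image_size) -> list[GroundTruthBox]:
    """YOLO-txt -> pixel ground-truth boxes for a (width, height) image."""
    w_img, h_img = image_size
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 5 fields, got {len(parts)}")
        cls = int(parts[0])
        cx, cy, w, h = map(float, parts[1:])
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"line {lineno}: normalized value {v} out of [0, 1]")
        boxes.append(GroundTruthBox(
            xmin=(cx - w / 2) * w_img, ymin=(cy - h / 2) * h_img,
            xmax=(cx + w / 2) * w_img, ymax=(cy + h / 2) * h_img,
            class_id=cls))
    return boxes


def write_yolo_annotations(path, boxes, image_size) -> None:
    w_img, h_img = image_size
    lines = []
    for b in boxes:
        box = getattr(b, "box", b)
        cls = getattr(b, "class_id", 0)
        if not (0.0 <= box[0] < box[2] <= w_img and 0.0 <= box[1] < box[3] <= h_img):
            raise ValueError(f"box {box} does not fit inside image {image_size}")
        cx = (box[0] + box[2]) / 2.0 / w_img
        cy = (box[1] + box[3]) / 2.0 / h_img
        w = (box[2] - box[0]) / w_img
        h = (box[3] - box[1]) / h_img
        lines.append(f"{cls} {cx:.8f} {cy:.8f} {w:.8f} {h:.8f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _save_npz(path, arrays: dict, meta: dict) -> None:
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def _load_npz(path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"][()]))
        arrays = {k: z[k] for k in z.files if k != "meta"}
    return arrays, meta


def save_regressor_archive(path, model, scaler: FeatureScaler) -> None:
    spec: RegressorSpec = model.spec
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays.update(x_mean=scaler.x_mean, x_std=scaler.x_std,
                  y_mean=scaler.y_mean, y_std=scaler.y_std)
    meta = {"kind": "regressor", "variant": spec.variant,
            "hidden_widths": list(spec.hidden_widths),
            "trained": bool(getattr(model, "trained", False))}
    _save_npz(path, arrays, meta)


def load_regressor_archive(path):
    arrays, meta = _load_npz(path)
    if meta.get("kind") != "regressor":
        raise ValueError(f"{path} is not a regressor archive")
    spec = RegressorSpec(variant=meta["variant"],
                         hidden_widths=tuple(meta["hidden_widths"]))
    model = build_regressor(spec)
    for i, p in enumerate(model.params()):
        p.value[...] = arrays[f"p{i}"]
    model.trained = meta["trained"]
    scaler = FeatureScaler(x_mean=arrays["x_mean"], x_std=arrays["x_std"],
                           y_mean=arrays["y_mean"], y_std=arrays["y_std"])
    return model, scaler


def save_detector_archive(path, model: CustomYOLO) -> None:
    cfg = model.cfg
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    meta = {"kind": "detector", "config": {
        "input_size": cfg.input_size, "in_channels": cfg.in_channels,
        "stage_channels": list(cfg.stage_channels),
        "se_reduction": cfg.se_reduction,
        "anchors": [list(a) for a in cfg.anchors],
        "num_classes": cfg.num_classes,
        "conf_threshold": cfg.conf_threshold,
        "nms_iou_threshold": cfg.nms_iou_threshold}}
    _save_npz(path, arrays, meta)


def load_detector_archive(path) -> CustomYOLO:
    arrays, meta = _load_npz(path)
    if meta.get("kind") != "detector":
        raise ValueError(f"{path} is not a detector archive")
    c = meta["config"]
    cfg = DetectorConfig(input_size=c["input_size"], in_channels=c["in_channels"],
                         stage_channels=tuple(c["stage_channels"]),
                         se_reduction=c["se_reduction"],
                         anchors=tuple(tuple(a) for a in c["anchors"]),
                         num_classes=c["num_classes"],
                         conf_threshold=c["conf_threshold"],
                         nms_iou_threshold=c["nms_iou_threshold"])
    model = CustomYOLO(cfg)
    for i, p in enumerate(model.params()):
        p.value[...] = arrays[f"p{i}"].astype(p.value.dtype)
    return model


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def save_png(path, image) -> None:
    """Write an (H, W, 3) float [0, 1] array as PNG."""
    from PIL import Image

    arr = (np.clip(np.asarray(image), 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_png(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
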