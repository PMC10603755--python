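"""Detection and localization metrics.

VOC-style average precision (all-point interpolation), box IoU,
parameter-reduction arithmetic for model-streamlining comparisons, and
per-axis (longitude / latitude) localization error reports.  The single
animal class makes mAP equal to AP here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ptz import EARTH_METERS_PER_DEGREE, GeoPoint, world_to_geo
from .regression import error_stats, predict_batch
from .ptz import CoordRecord

__all__ = [
    "iou",
    "average_precision",
    "percent_reduction",
    "LocalizationErrorReport",
    "localization_error_report",
    "evaluate_pipeline",
    "PUBLISHED_PARAM_TOTALS",
    "published_reduction_table",
]

# Published total parameter counts for the three backbone families,
# before and after streamlining the neck/head (model name -> params).
PUBLISHED_PARAM_TOTALS = {
    "CSPDarkNet-53": (63_937_686, 30_943_462),
    "MobileNetv3": (42_231_118, 9_623_966),
    "ShallowSE": (37_205_070, 4_556_458),
}


def iou(a, b) -> float:
    """Intersection over union of two (xmin, ymin, xmax, ymax) boxes
    under the half-open edge convention."""
    a = getattr(a, "box", a)
    b = getattr(b, "box", b)
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union if union > 0 else 0.0


def average_precision(dets, gts, iou_threshold: float = 0.5) -> float:
    """All-point interpolated AP for one class over a set of images.

    ``dets`` is a list per image of objects with ``.box`` and
    ``.confidence``; ``gts`` a list per image of ground-truth boxes.
    Detections are ranked by confidence globally; each ground truth can
    match at most one detection (greedy, highest-confidence first).
    """
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground-truth boxes")
    flat = []
    for img_idx, img_dets in enumerate(dets):
        for d in img_dets:
            flat.append((float(d.confidence), img_idx, d))
    flat.sort(key=lambda t: -t[0])
    matched = [set() for _ in gts]
    tp = np.zeros(len(flat))
    fp = np.zeros(len(flat))
    for r, (_, img_idx, d) in enumerate(flat):
        best_iou, best_g = 0.0, -1
        for g_idx, g in enumerate(gts[img_idx]):
            if g_idx in matched[img_idx]:
                continue
            v = iou(d, g)
            if v > best_iou:
                best_iou, best_g = v, g_idx
        if best_iou >= iou_threshold and best_g >= 0:
            matched[img_idx].add(best_g)
            tp[r] = 1.0
        else:
            fp[r] = 1.0
    if len(flat) == 0:
        return 0.0
    ctp = np.cumsum(tp)
    cfp = np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # all-point interpolation: precision envelope integrated over recall
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def percent_reduction(params_small: int, params_large: int) -> float:
    """Percentage parameter saving, 100 * (1 - small/large), to 2 decimals."""
    if params_large <= 0:
        raise ValueError("reference parameter count must be positive")
    return round(100.0 * (1.0 - params_small / params_large), 2)


def published_reduction_table() -> dict:
    """Streamlining savings recomputed from the published totals."""
    return {name: percent_reduction(small, large)
            for name, (large, small) in PUBLISHED_PARAM_TOTALS.items()}


@dataclass(frozen=True)
class LocalizationErrorReport:
    """Per-axis ground-distance error statistics, meters."""

    longitude_max: float
    longitude_avg: float
    latitude_max: float
    latitude_avg: float

    def __post_init__(self):
        for avg, mx in ((self.longitude_avg, self.longitude_max),
                        (self.latitude_avg, self.latitude_max)):
            if not 0.0 <= avg <= mx:
                raise ValueError("require 0 <= average <= maximum per axis")

    def as_dict(self):
        return {"longitude": {"max_m": self.longitude_max, "avg_m": self.longitude_avg},
                "latitude": {"max_m": self.latitude_max, "avg_m": self.latitude_avg}}


def localization_error_report(pred_geo, true_geo) -> LocalizationErrorReport:
    """East-west and north-south ground distances between paired fixes.

    Longitude-axis error = |dlon| * 111320 * cos(lat); latitude-axis
    error = |dlat| * 111320, evaluated at each true fix's latitude.
    """
    if len(pred_geo) != len(true_geo) or len(pred_geo) == 0:
        raise ValueError("geo lists must be equal-length and non-empty")
    lon_err, lat_err = [], []
    for p, t in zip(pred_geo, true_geo):
        coslat = math.cos(math.radians(t.latitude))
        lon_err.append(abs(p.longitude - t.longitude) * EARTH_METERS_PER_DEGREE * coslat)
        lat_err.append(abs(p.latitude - t.latitude) * EARTH_METERS_PER_DEGREE)
    lon = np.asarray(lon_err)
    lat = np.asarray(lat_err)
    return LocalizationErrorReport(longitude_max=float(lon.max()),
                                   longitude_avg=float(lon.mean()),
                                   latitude_max=float(lat.max()),
                                   latitude_avg=float(lat.mean()))


def evaluate_pipeline(detector, regressor, scaler, frames, truth,
                      origin: GeoPoint = GeoPoint(39.5, 107.9),
                      iou_threshold: float = 0.5, match_gate_m: float = 5.0):
    """Run detect -> regress -> geolocate over posed frames and score it.

    ``frames`` is a sequence of dicts with keys ``image`` ((H, W, 3) or
    (3, H, W) float array), ``camera`` (CameraModel pose metadata) and
    ``gt_boxes`` (GroundTruthBox list); ``truth`` gives, per frame, the
    (n_i, 2) true world positions of the boxed animals, index-aligned
    with ``gt_boxes``.  Detection quality is scored as AP at the given
    IoU threshold.  Each detection is turned into a coordinate record
    using the frame's pose, regressed to (Xw, Zw), and matched to the
    nearest true position; pairs farther than ``match_gate_m`` meters are
    excluded from localization scoring.  Returns a dict with the AP, the
    Euclidean error stats, the per-axis geo report and match counts.
    """
    import numpy as _np

    all_dets, all_gts = [], []
    pred_world, true_world = [], []
    for frame, frame_truth in zip(frames, truth):
        cam = frame.get("camera")
        if cam is None:
            raise ValueError(f"frame {frame.get('name', '?')} is missing camera pose metadata")
        img = _np.asarray(frame["image"], dtype=_np.float32)
        if img.ndim == 3 and img.shape[2] in (1, 3):
            img = _np.transpose(img, (2, 0, 1))
        dets = detector.detect(img)
        all_dets.append(dets)
        all_gts.append(frame["gt_boxes"])
        frame_truth = _np.asarray(frame_truth, dtype=float).reshape(-1, 2)
        for d in dets:
            rec = CoordRecord(num=1, xmin=d.xmin, ymin=d.ymin, xmax=d.xmax,
                              ymax=d.ymax, pan=cam.pan, tilt=cam.tilt,
                              zoom=cam.zoom, xw=0.0, zw=0.0)
            pw = _np.asarray(predict_batch(regressor, scaler, [rec])[0])
            if len(frame_truth) == 0:
                continue
            dist = _np.hypot(frame_truth[:, 0] - pw[0], frame_truth[:, 1] - pw[1])
            j = int(dist.argmin())
            if dist[j] <= match_gate_m:
                pred_world.append(pw)
                true_world.append(frame_truth[j])
    try:
        ap = average_precision(all_dets, all_gts, iou_threshold=iou_threshold)
    except ValueError:
        ap = float("nan")
    result = {"ap": ap, "n_detections": sum(len(d) for d in all_dets),
              "n_localized": len(pred_world)}
    if pred_world:
        pred_world = _np.asarray(pred_world)
        true_world = _np.asarray(true_world)
        result["error_stats"] = error_stats(pred_world, true_world)
        pred_geo = [world_to_geo(p, origin) for p in pred_world]
        true_geo = [world_to_geo(t, origin) for t in true_world]
        result["geo_report"] = localization_error_report(pred_geo, true_geo)
    else:
        result["error_stats"] = None
        result["geo_report"] = None
        result["empty"] = True
    return result
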