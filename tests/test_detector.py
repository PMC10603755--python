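"""Detector construction, decode/NMS oracles, loss and training behavior."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

import goatloc as gl
from goatloc.counting import count_parameters
from goatloc.detector import (STRIDE, CustomYOLO, Detection, DetectorConfig,
                              GroundTruthBox, RawHeadOutput, build_custom_yolo,
                              build_shallowse, custom_yolo_layer_specs,
                              decode_predictions, detection_loss, kmeans_anchors,
                              nms, train_detector)
from goatloc.layers import n_params

SMALL_CFG = DetectorConfig(input_size=32, stage_channels=(4, 4, 8, 8, 8),
                           se_reduction=2, anchors=((10.0, 8.0), (16.0, 12.0)))


class TestBuild:
    def test_backbone_output_is_stride_16(self):
        cfg = DetectorConfig(input_size=416)
        bb = build_shallowse(cfg, rng=0)
        out = bb.forward(np.zeros((1, 3, 416, 416), dtype=np.float32))
        assert out.shape[2:] == (26, 26)

    def test_closed_form_count_equals_weight_enumeration(self):
        for model in (build_shallowse(SMALL_CFG, rng=0),
                      build_custom_yolo(SMALL_CFG, rng=0)):
            assert count_parameters(model.layer_specs()) == n_params(model)

    def test_zero_image_forward_is_finite(self):
        model = build_custom_yolo(SMALL_CFG, rng=1)
        out = model.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))
        assert np.all(np.isfinite(out))

    def test_head_channel_count(self):
        cfg = DetectorConfig(num_classes=1, anchors=((10, 10), (20, 20), (30, 30)))
        assert cfg.head_channels == 3 * (5 + 1) == 18
        model = build_custom_yolo(SMALL_CFG, rng=0)
        out = model.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))
        assert out.shape[1] == SMALL_CFG.head_channels

    def test_neck_uses_three_convolutions(self):
        model = build_custom_yolo(SMALL_CFG, rng=0)
        assert model.neck_depth == 3
        n_convs = sum(1 for s in model.neck.layer_specs() if s.kind == "conv")
        assert n_convs == 3

    def test_streamlined_model_is_smaller_than_five_conv_three_head(self):
        cfg = DetectorConfig()
        slim = count_parameters(custom_yolo_layer_specs(cfg, streamlined=True))
        full = count_parameters(custom_yolo_layer_specs(cfg, streamlined=False))
        assert slim < full

    def test_bad_input_size_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=100)

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(anchors=())


def decode_oracle(grid, cfg, stride=STRIDE, thr=0.0):
    """Explicit per-cell loop decode."""
    hg, wg, _ = grid.shape
    a = len(cfg.anchors)
    out = []
    for i in range(hg):
        for j in range(wg):
            for k in range(a):
                v = grid[i, j, k * (5 + cfg.num_classes):(k + 1) * (5 + cfg.num_classes)]
                cx = (j + expit(v[0])) * stride
                cy = (i + expit(v[1])) * stride
                w = cfg.anchors[k][0] * math.exp(min(max(v[2], -8), 8))
                h = cfg.anchors[k][1] * math.exp(min(max(v[3], -8), 8))
                cls = expit(v[5:])
                cid = int(np.argmax(cls))
                conf = expit(v[4]) * cls[cid]
                box = (max(cx - w / 2, 0.0), max(cy - h / 2, 0.0),
                       min(cx + w / 2, cfg.input_size), min(cy + h / 2, cfg.input_size))
                if conf >= thr and box[0] < box[2] and box[1] < box[3]:
                    out.append((box, conf, cid))
    return out


class TestDecode:
    def test_zero_grid_centers_cells_with_anchor_sizes(self):
        cfg = SMALL_CFG
        grid = np.zeros((2, 2, cfg.head_channels))
        dets = decode_predictions(RawHeadOutput(grid), cfg, conf_threshold=0.0)
        assert len(dets) == 2 * 2 * cfg.n_anchors
        d = [x for x in dets
             if abs((x.xmin + x.xmax) / 2 - 0.5 * STRIDE) < 1e-9
             and abs((x.ymin + x.ymax) / 2 - 0.5 * STRIDE) < 1e-9]
        widths = sorted(x.xmax - x.xmin for x in d)
        assert np.allclose(widths, sorted(a[0] for a in cfg.anchors))

    def test_threshold_one_returns_nothing(self):
        grid = np.random.default_rng(0).normal(size=(2, 2, SMALL_CFG.head_channels))
        assert decode_predictions(RawHeadOutput(grid), SMALL_CFG, conf_threshold=1.0) == []

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(size=(2, 2, SMALL_CFG.head_channels))
        dets = decode_predictions(RawHeadOutput(grid), SMALL_CFG, conf_threshold=0.0)
        oracle = decode_oracle(grid, SMALL_CFG)
        assert len(dets) == len(oracle)
        got = sorted([(d.box, d.confidence) for d in dets])
        want = sorted([(b, c) for b, c, _ in oracle])
        for (gb, gc), (wb, wc) in zip(got, want):
            assert np.allclose(gb, wb, atol=1e-6)
            assert abs(gc - wc) < 1e-9

    def test_nonfinite_grid_rejected(self):
        grid = np.zeros((2, 2, SMALL_CFG.head_channels))
        grid[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            decode_predictions(RawHeadOutput(grid), SMALL_CFG)

    def test_decode_nms_boxes_stay_inside_frame(self):
        rng = np.random.default_rng(2)
        grid = rng.normal(scale=3.0, size=(2, 2, SMALL_CFG.head_channels))
        dets = nms(decode_predictions(RawHeadOutput(grid), SMALL_CFG, conf_threshold=0.0),
                   SMALL_CFG.nms_iou_threshold)
        for d in dets:
            assert 0 <= d.xmin < d.xmax <= SMALL_CFG.input_size
            assert 0 <= d.ymin < d.ymax <= SMALL_CFG.input_size


def nms_oracle(dets, thr):
    """Iterative global-argmax reference suppression."""
    remaining = list(dets)
    kept = []
    while remaining:
        best = max(remaining, key=lambda d: d.confidence)
        kept.append(best)
        remaining = [d for d in remaining
                     if d is not best and (d.class_id != best.class_id
                                           or gl.iou(d, best) <= thr)]
    return kept


class TestNMS:
    def test_duplicate_boxes_keep_stronger(self):
        a = Detection(0, 0, 10, 10, 0.9)
        b = Detection(0, 0, 10, 10, 0.7)
        assert nms([a, b], 0.45) == [a]

    def test_disjoint_boxes_all_survive(self):
        dets = [Detection(i * 20, 0, i * 20 + 10, 10, 0.5 + 0.01 * i) for i in range(4)]
        assert len(nms(dets, 0.45)) == 4

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dets = []
            for _ in range(20):
                x, y = rng.uniform(0, 80, 2)
                w, h = rng.uniform(5, 30, 2)
                dets.append(Detection(x, y, x + w, y + h, float(rng.uniform(0.01, 1.0))))
            got = nms(dets, 0.45)
            want = nms_oracle(dets, 0.45)
            assert [d.box for d in got] == [d.box for d in want]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        dets = [Detection(x, y, x + w, y + h, float(c))
                for x, y, w, h, c in zip(rng.uniform(0, 50, 15), rng.uniform(0, 50, 15),
                                         rng.uniform(5, 25, 15), rng.uniform(5, 25, 15),
                                         rng.uniform(0.05, 1, 15))]
        once = nms(dets, 0.45)
        assert nms(once, 0.45) == once


class TestLoss:
    def _perfect_grid(self, cfg, target):
        """Raw grid that decodes exactly to the target with saturated scores."""
        grid = np.full((cfg.grid_size, cfg.grid_size, cfg.head_channels), -12.0)
        cx, cy = (target.xmin + target.xmax) / 2, (target.ymin + target.ymax) / 2
        w, h = target.xmax - target.xmin, target.ymax - target.ymin
        j, i = int(cx // STRIDE), int(cy // STRIDE)
        ious = [min(a[0], w) * min(a[1], h) / (a[0] * a[1] + w * h - min(a[0], w) * min(a[1], h))
                for a in cfg.anchors]
        k = int(np.argmax(ious))
        base = k * (5 + cfg.num_classes)
        grid[i, j, base + 0] = logit(cx / STRIDE - j)
        grid[i, j, base + 1] = logit(cy / STRIDE - i)
        grid[i, j, base + 2] = math.log(w / cfg.anchors[k][0])
        grid[i, j, base + 3] = math.log(h / cfg.anchors[k][1])
        grid[i, j, base + 4] = 12.0
        grid[i, j, base + 5 + target.class_id] = 12.0
        return grid

    def test_perfect_prediction_has_near_zero_loss(self):
        cfg = SMALL_CFG
        t = GroundTruthBox(6.0, 4.0, 17.0, 13.0)
        loss = detection_loss(self._perfect_grid(cfg, t), [t], cfg)
        assert loss < 1e-3

    def test_loss_nonnegative_and_finite_on_random_input(self):
        rng = np.random.default_rng(5)
        cfg = SMALL_CFG
        for _ in range(5):
            grid = rng.normal(size=(2, 2, cfg.head_channels))
            ts = [GroundTruthBox(2, 2, 14, 10), GroundTruthBox(16, 18, 30, 30)]
            loss = detection_loss(grid, ts, cfg)
            assert np.isfinite(loss) and loss >= 0.0

    def test_no_targets_loss_vanishes_with_suppressed_objectness(self):
        cfg = SMALL_CFG
        grid = np.zeros((2, 2, cfg.head_channels))
        grid[..., 4::5 + cfg.num_classes] = -20.0
        assert detection_loss(grid, [], cfg) < 1e-6

    def test_degenerate_target_skipped_with_warning(self):
        cfg = SMALL_CFG
        grid = np.zeros((2, 2, cfg.head_channels))
        # zero-area target constructed past the dataclass validation
        t = GroundTruthBox(1.0, 1.0, 2.0, 2.0)
        t.xmax = 1.0
        with pytest.warns(UserWarning):
            detection_loss(grid, [t], cfg)

    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        cfg = SMALL_CFG
        grid = rng.normal(size=(2, 2, cfg.head_channels))
        ts = [GroundTruthBox(3, 3, 15, 12)]
        _, grad = detection_loss(grid, ts, cfg, return_grad=True)
        num = np.zeros_like(grid)
        eps = 1e-5
        it = np.nditer(grid, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = grid[idx]
            grid[idx] = orig + eps
            hi = detection_loss(grid, ts, cfg)
            grid[idx] = orig - eps
            lo = detection_loss(grid, ts, cfg)
            grid[idx] = orig
            num[idx] = (hi - lo) / (2 * eps)
        assert np.allclose(grad, num, atol=1e-4)


def tiny_dataset(n=6, size=32, seed=0):
    cams, traj = gl.near_field_scenario(n, seed=seed, image_size=size, n_goats=4)
    data = []
    for t, (cam, flock) in enumerate(zip(cams, traj)):
        img, boxes = gl.render_scene(cam, flock, seed=500 + t)
        data.append((img, [GroundTruthBox(*b) for b in boxes]))
    return [d for d in data if d[1]]


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_detector([], SMALL_CFG)

    def test_zero_learning_rate_freezes_loss(self):
        data = tiny_dataset()
        _, hist = train_detector(data, SMALL_CFG, epochs=3, lr=0.0, seed=0)
        assert np.allclose(hist, hist[0])

    def test_fixed_seed_is_bitwise_reproducible(self):
        data = tiny_dataset()
        _, h1 = train_detector(data, SMALL_CFG, epochs=2, seed=4)
        _, h2 = train_detector(data, SMALL_CFG, epochs=2, seed=4)
        assert h1 == h2

    def test_loss_decreases_on_tiny_fixture(self):
        data = tiny_dataset()
        _, hist = train_detector(data, SMALL_CFG, epochs=15, seed=0)
        assert hist[-1] < hist[0]


class TestAnchors:
    def test_kmeans_recovers_separated_clusters(self):
        rng = np.random.default_rng(7)
        wh = np.concatenate([rng.normal((10, 8), 0.3, size=(40, 2)),
                             rng.normal((30, 22), 0.5, size=(40, 2)),
                             rng.normal((80, 60), 1.0, size=(40, 2))])
        anchors = kmeans_anchors(wh, k=3, seed=0)
        for got, want in zip(anchors, ((10, 8), (30, 22), (80, 60))):
            assert np.allclose(got, want, atol=1.0)

    def test_fallback_with_few_boxes(self):
        anchors = kmeans_anchors([(20.0, 15.0)], k=3)
        assert len(anchors) == 3 and all(w > 0 and h > 0 for w, h in anchors)
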