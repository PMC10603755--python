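import numpy as np
import pytest

import goatloc as gl
from goatloc.detector import DetectorConfig, GroundTruthBox, kmeans_anchors, train_detector

FIXTURE_IMAGE_SIZE = 96
FIXTURE_STAGE_CHANNELS = (8, 16, 32, 48, 64)


def render_fixture_set(n_frames, scenario_seed, render_seed_base, image_size=FIXTURE_IMAGE_SIZE):
    """Rendered frames + ground-truth boxes + camera poses + goat positions."""
    cams, traj = gl.near_field_scenario(n_frames, seed=scenario_seed,
                                        image_size=image_size)
    frames = []
    for t, (cam, flock) in enumerate(zip(cams, traj)):
        img, boxes = gl.render_scene(cam, flock, seed=render_seed_base + t)
        frames.append({"image": img, "camera": cam,
                       "gt_boxes": [GroundTruthBox(*b) for b in boxes],
                       "positions": flock})
    return frames


@pytest.fixture(scope="session")
def blob_training_set():
    """50 synthetic flock frames for detector training."""
    return render_fixture_set(50, scenario_seed=5, render_seed_base=1000)


@pytest.fixture(scope="session")
def trained_detector(blob_training_set):
    """Detector trained for 100 epochs on the 50-frame fixture set.

    Session-scoped because training dominates suite runtime; shared by
    the detection-accuracy and end-to-end localization checks.
    """
    dataset = [(f["image"], f["gt_boxes"]) for f in blob_training_set]
    wh = [(b.xmax - b.xmin, b.ymax - b.ymin) for _, bs in dataset for b in bs]
    cfg = DetectorConfig(input_size=FIXTURE_IMAGE_SIZE,
                         stage_channels=FIXTURE_STAGE_CHANNELS,
                         anchors=kmeans_anchors(wh, k=3, seed=0),
                         conf_threshold=0.05)
    model, history = train_detector(dataset, cfg, epochs=100, seed=0)
    return model, cfg, history
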