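"""Synthetic PTZ acquisition model.

Emulates a pan-tilt-zoom camera mounted ~15.6 m above a pasture watching
a small flock (11 animals by default) grazing on the ground plane.  The
module provides the forward geometry (world -> pixel pinhole projection
under a pan/tilt/zoom pose), a correlated-random-walk flock simulator,
generation of coordinate-regression records (bounding box + pose ->
world position, with GPS-grade noise), rendered fixture images for
detector training, and the local tangent-plane conversion between world
meters and longitude/latitude.

World frame: origin at the camera base, Xw east, Zw north, Yw up; the
ground plane is Yw = 0.  Pan is measured clockwise from north, tilt is
positive downward, and zoom divides the base horizontal field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CameraModel",
    "GoatShape",
    "GeoPoint",
    "CoordRecord",
    "CoordDataset",
    "project_world_to_pixel",
    "goat_bbox",
    "simulate_flock",
    "track_schedule",
    "generate_coord_dataset",
    "render_scene",
    "world_to_geo",
    "geo_to_world",
    "near_field_scenario",
    "far_field_scenario",
]

EARTH_METERS_PER_DEGREE = 111320.0


@dataclass(frozen=True)
class CameraModel:
    """PTZ pose plus fixed intrinsics and mount height."""

    mount_height: float = 15.6  # meters above the ground plane
    base_hfov: float = 60.0  # horizontal field of view in degrees at zoom 1
    image_width: int = 416
    image_height: int = 416
    pan: float = 0.0  # degrees clockwise from north
    tilt: float = 0.0  # degrees below the horizon
    zoom: float = 1.0  # focal multiplier; effective hfov = base_hfov / zoom

    def __post_init__(self):
        if not self.zoom > 0:
            raise ValueError("zoom must be positive")
        if not 0.0 < self.base_hfov / self.zoom < 180.0:
            raise ValueError("effective field of view must lie in (0, 180) degrees")

    @property
    def focal_px(self) -> float:
        half = math.radians(self.base_hfov / self.zoom) / 2.0
        return (self.image_width / 2.0) / math.tan(half)


@dataclass(frozen=True)
class GoatShape:
    """Physical extent of one animal used to synthesize bounding boxes."""

    body_length: float = 1.2  # meters
    body_height: float = 0.8  # meters

    def __post_init__(self):
        if self.body_length <= 0 or self.body_height <= 0:
            raise ValueError("goat dimensions must be positive")


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float

    def __post_init__(self):
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError("latitude/longitude out of range")


@dataclass
class CoordRecord:
    """One coordinate-conversion sample: 7 regression inputs + targets.

    ``xw``/``zw`` may be None, mirroring the occasional missing GPS fixes
    in field recordings (written as ``--`` in the CSV dialect).
    """

    num: int
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    pan: float
    tilt: float
    zoom: float
    xw: float | None = None
    zw: float | None = None

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("degenerate bounding box in coordinate record")
        if not self.zoom > 0:
            raise ValueError("zoom must be positive")

    @property
    def complete(self) -> bool:
        return self.xw is not None and self.zw is not None

    def inputs(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax,
                         self.pan, self.tilt, self.zoom])

    def targets(self) -> np.ndarray:
        if not self.complete:
            raise ValueError("record has missing world coordinates")
        return np.array([self.xw, self.zw])


@dataclass
class CoordDataset:
    """Records plus noiseless ground truth and provenance indices."""

    records: list[CoordRecord]
    truth: np.ndarray  # (n, 2) true (Xw, Zw) before GPS noise
    frame_index: np.ndarray  # (n,) frame each record came from
    goat_index: np.ndarray  # (n,) animal each record came from


def _camera_coords(cam: CameraModel, p) -> np.ndarray:
    """Offset from the camera center expressed in the camera frame.

    Returns (x_right, y_down, z_forward) in meters.
    """
    p = np.asarray(p, dtype=float)
    d = p - np.array([0.0, cam.mount_height, 0.0])
    if np.allclose(d, 0.0):
        raise ValueError("point coincides with the camera center")
    psi = math.radians(cam.pan)
    tau = math.radians(cam.tilt)
    # yaw about the vertical axis: bearing `pan` maps onto the forward axis
    d1x = d[0] * math.cos(psi) - d[2] * math.sin(psi)
    d1y = d[1]
    d1z = d[0] * math.sin(psi) + d[2] * math.cos(psi)
    # tilt about the camera's right axis, positive pitching down
    x_cam = d1x
    y_cam = -math.cos(tau) * d1y - math.sin(tau) * d1z
    z_cam = -math.sin(tau) * d1y + math.cos(tau) * d1z
    return np.array([x_cam, y_cam, z_cam])


def _project(cam: CameraModel, p):
    """Project to pixels without a visibility check; None if behind the camera."""
    x_cam, y_cam, z_cam = _camera_coords(cam, p)
    if z_cam <= 1e-9:
        return None
    f = cam.focal_px
    u = cam.image_width / 2.0 + f * x_cam / z_cam
    v = cam.image_height / 2.0 + f * y_cam / z_cam
    return u, v


def project_world_to_pixel(cam: CameraModel, p):
    """Pinhole projection of a world point; None when outside the frame."""
    uv = _project(cam, p)
    if uv is None:
        return None
    u, v = uv
    if not (0 <= u < cam.image_width and 0 <= v < cam.image_height):
        return None
    return u, v


def goat_bbox(cam: CameraModel, p, shape: GoatShape = GoatShape()):
    """Pixel envelope of the animal's upright 3-D box, clipped to the frame.

    The footprint is a square of side ``body_length`` centered at the
    ground position; the 8 corners are projected and their 2-D min/max
    envelope is intersected with the image.  Returns
    (xmin, ymin, xmax, ymax) or None when fully out of view.
    """
    p = np.asarray(p, dtype=float)
    hx = shape.body_length / 2.0
    corners = []
    for dx in (-hx, hx):
        for dy in (0.0, shape.body_height):
            for dz in (-hx, hx):
                uv = _project(cam, p + np.array([dx, dy, dz]))
                if uv is None:
                    return None
                corners.append(uv)
    corners = np.asarray(corners)
    xmin, ymin = corners.min(axis=0)
    xmax, ymax = corners.max(axis=0)
    xmin = max(xmin, 0.0)
    ymin = max(ymin, 0.0)
    xmax = min(xmax, float(cam.image_width))
    ymax = min(ymax, float(cam.image_height))
    if xmin >= xmax or ymin >= ymax:
        return None
    return xmin, ymin, xmax, ymax


def simulate_flock(n_goats: int = 11, n_steps: int = 100, step_std: float = 0.15,
                   seed=None, *, phi: float = 0.7, cohesion: float = 0.02,
                   center=(0.0, 60.0), spread: float = 8.0,
                   arena_half: float = 1e6) -> np.ndarray:
    """Correlated random walk with centroid cohesion for a grazing flock.

    Per animal, the step (velocity) follows an AR(1) process with
    autocorrelation ``phi`` whose stationary per-axis standard deviation
    is ``step_std`` meters/step, plus a pull toward the flock centroid of
    strength ``cohesion`` (in units of step_std per meter of offset, so a
    zero step_std flock is exactly stationary).  Positions are clipped to
    a square arena of half-side ``arena_half`` around ``center``.

    Returns trajectories of shape (n_steps, n_goats, 2) holding (Xw, Zw).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    pos = center + rng.normal(0.0, spread, size=(n_goats, 2))
    innov_std = step_std * math.sqrt(max(1.0 - phi * phi, 0.0))
    vel = rng.normal(0.0, step_std, size=(n_goats, 2))  # stationary init
    out = np.empty((n_steps, n_goats, 2))
    out[0] = pos
    for t in range(1, n_steps):
        centroid = pos.mean(axis=0)
        pull = cohesion * step_std * (centroid - pos)
        vel = phi * vel + pull + rng.normal(0.0, innov_std, size=(n_goats, 2))
        pos = pos + vel
        pos = np.clip(pos, center - arena_half, center + arena_half)
        out[t] = pos
    return out


def track_schedule(trajectories: np.ndarray, *, mount_height: float = 15.6,
                   base_hfov: float = 60.0, image_size: int = 416,
                   zoom_range=(2.0, 4.0), pan_jitter: float = 1.0,
                   tilt_jitter: float = 0.5, seed=None) -> list[CameraModel]:
    """Per-frame camera poses that loosely track the flock centroid.

    Pan/tilt aim at the centroid with Gaussian jitter (degrees); zoom is
    drawn uniformly per frame from ``zoom_range``, emulating an operator
    reframing the flock.
    """
    rng = np.random.default_rng(seed)
    cams = []
    for frame in trajectories:
        cx, cz = frame.mean(axis=0)
        dist = math.hypot(cx, cz)
        pan = math.degrees(math.atan2(cx, cz)) + rng.normal(0.0, pan_jitter)
        tilt = math.degrees(math.atan2(mount_height, dist)) + rng.normal(0.0, tilt_jitter)
        zoom = rng.uniform(*zoom_range)
        cams.append(CameraModel(mount_height=mount_height, base_hfov=base_hfov,
                                image_width=image_size, image_height=image_size,
                                pan=pan, tilt=tilt, zoom=zoom))
    return cams


def generate_coord_dataset(cam_schedule, trajectories, gps_noise_std: float = 1.5,
                           seed=None, *, shape: GoatShape = GoatShape(),
                           pixel_jitter_std: float = 1.0,
                           missing_rate: float = 0.05,
                           min_box_px: float = 2.0) -> CoordDataset:
    """Emit coordinate-regression records for every visible goat/frame.

    Each record couples the (optionally pixel-jittered) projected box and
    the camera pose with the animal's world position corrupted by
    isotropic Gaussian GPS noise of ``gps_noise_std`` meters (the field
    locator's rated accuracy is 1.5 m).  A fraction ``missing_rate`` of
    records loses its Xw and/or Zw fix, mirroring dropouts in real logs.
    """
    if len(cam_schedule) != len(trajectories):
        raise ValueError("camera schedule and trajectories must be time-aligned")
    rng = np.random.default_rng(seed)
    records, truth, f_idx, g_idx = [], [], [], []
    num = 0
    for t, (cam, frame) in enumerate(zip(cam_schedule, trajectories)):
        for g, (xw, zw) in enumerate(frame):
            box = goat_bbox(cam, (xw, 0.0, zw), shape)
            if box is None:
                continue
            xmin, ymin, xmax, ymax = box
            if xmax - xmin < min_box_px or ymax - ymin < min_box_px:
                continue
            if pixel_jitter_std > 0:
                j = rng.normal(0.0, pixel_jitter_std, size=4)
                xmin, ymin, xmax, ymax = xmin + j[0], ymin + j[1], xmax + j[2], ymax + j[3]
                if xmax - xmin < 1.0:
                    xmax = xmin + 1.0
                if ymax - ymin < 1.0:
                    ymax = ymin + 1.0
            noise = rng.normal(0.0, gps_noise_std, size=2) if gps_noise_std > 0 else (0.0, 0.0)
            rx: float | None = xw + noise[0]
            rz: float | None = zw + noise[1]
            if missing_rate > 0:
                if rng.random() < missing_rate:
                    rx = None
                if rng.random() < missing_rate:
                    rz = None
            num += 1
            records.append(CoordRecord(num=num, xmin=xmin, ymin=ymin, xmax=xmax,
                                       ymax=ymax, pan=cam.pan, tilt=cam.tilt,
                                       zoom=cam.zoom, xw=rx, zw=rz))
            truth.append((xw, zw))
            f_idx.append(t)
            g_idx.append(g)
    return CoordDataset(records=records,
                        truth=np.asarray(truth, dtype=float).reshape(-1, 2),
                        frame_index=np.asarray(f_idx, dtype=int),
                        goat_index=np.asarray(g_idx, dtype=int))


def render_scene(cam: CameraModel, goat_positions, shape: GoatShape = GoatShape(),
                 seed=None, min_box_px: float = 3.0):
    """Grass-textured frame with light elliptical goat blobs.

    Returns (image, boxes): an (H, W, 3) float array in [0, 1] and the
    matching ground-truth boxes as (xmin, ymin, xmax, ymax) tuples in the
    order the blobs were painted (far to near).  Not photo-realistic —
    just enough structure for a detector to have something to learn.
    """
    rng = np.random.default_rng(seed)
    h, w = cam.image_height, cam.image_width
    base = np.array([0.32, 0.42, 0.24])
    img = np.empty((h, w, 3))
    coarse = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=3.0)
    fine = rng.normal(0.0, 1.0, size=(h, w))
    tex = 0.10 * coarse / max(coarse.std(), 1e-9) + 0.03 * fine
    for ch in range(3):
        img[:, :, ch] = base[ch] * (1.0 + tex)
    items = []
    for p in np.asarray(goat_positions, dtype=float):
        pos = np.array([p[0], 0.0, p[1]])
        box = goat_bbox(cam, pos, shape)
        if box is None:
            continue
        if box[2] - box[0] < min_box_px or box[3] - box[1] < min_box_px:
            continue
        depth = _camera_coords(cam, pos)[2]
        items.append((depth, box))
    items.sort(key=lambda it: -it[0])  # paint far goats first
    boxes = []
    yy, xx = np.mgrid[0:h, 0:w]
    for _, (xmin, ymin, xmax, ymax) in items:
        cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
        ax, ay = max((xmax - xmin) / 2.0, 1.0), max((ymax - ymin) / 2.0, 1.0)
        mask = ((xx + 0.5 - cx) / ax) ** 2 + ((yy + 0.5 - cy) / ay) ** 2 <= 1.0
        shade = rng.uniform(0.82, 0.95)
        color = np.array([shade, shade, shade * rng.uniform(0.96, 1.0)])
        img[mask] = color * (1.0 + 0.04 * fine[mask])[:, None]
        boxes.append((xmin, ymin, xmax, ymax))
    np.clip(img, 0.0, 1.0, out=img)
    return img, boxes


def world_to_geo(p, origin: GeoPoint) -> GeoPoint:
    """Local equirectangular conversion of (Xw east, Zw north) meters."""
    xw, zw = float(p[0]), float(p[-1])  # accepts (xw, zw) or (xw, yw, zw)
    coslat = math.cos(math.radians(origin.latitude))
    if abs(coslat) < 1e-9:
        raise ValueError("origin too close to a pole for equirectangular mapping")
    return GeoPoint(latitude=origin.latitude + zw / EARTH_METERS_PER_DEGREE,
                    longitude=origin.longitude + xw / (EARTH_METERS_PER_DEGREE * coslat))


def geo_to_world(g: GeoPoint, origin: GeoPoint):
    """Inverse of :func:`world_to_geo`; returns (xw, zw) meters."""
    coslat = math.cos(math.radians(origin.latitude))
    if abs(coslat) < 1e-9:
        raise ValueError("origin too close to a pole for equirectangular mapping")
    zw = (g.latitude - origin.latitude) * EARTH_METERS_PER_DEGREE
    xw = (g.longitude - origin.longitude) * EARTH_METERS_PER_DEGREE * coslat
    return xw, zw


def near_field_scenario(n_frames: int, seed=0, *, image_size: int = 64,
                        n_goats: int = 11):
    """Close-range fixture: flock ~40-80 m out, moderate zoom, small frames.

    Used for detector training fixtures and end-to-end localization,
    where each animal must span a learnable number of pixels.
    """
    traj = simulate_flock(n_goats=n_goats, n_steps=n_frames, step_std=0.15,
                          seed=seed, center=(10.0, 55.0), spread=7.0)
    cams = track_schedule(traj, image_size=image_size, zoom_range=(6.0, 9.0),
                          pan_jitter=1.2, tilt_jitter=0.4, seed=seed + 1)
    return cams, traj


def far_field_scenario(n_frames: int, seed=0, *, image_size: int = 416,
                       n_goats: int = 11):
    """Far-range fixture shaped like the field logs: ~250-400 m, high zoom.

    Pan/tilt/zoom magnitudes match the published coordinate table (pan
    ~145 deg, tilt a few degrees, zoom up to ~18); world coordinates come
    out at negative hundreds of meters in the camera-base frame.
    """
    bearing = math.radians(145.6)
    center = (330.0 * math.sin(bearing), 330.0 * math.cos(bearing))
    traj = simulate_flock(n_goats=n_goats, n_steps=n_frames, step_std=0.2,
                          seed=seed, center=center, spread=15.0)
    cams = track_schedule(traj, image_size=image_size, zoom_range=(3.8, 18.4),
                          pan_jitter=0.8, tilt_jitter=0.3, seed=seed + 1)
    return cams, traj
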