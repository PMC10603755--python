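"""Simulate a grazing flock under a PTZ camera and emit coordinate records.

Eleven animals follow a correlated random walk ~55 m from a camera
mounted 15.6 m up; the camera tracks the flock centroid.  Each visible
animal yields one record coupling its projected bounding box and the
camera pose with its GPS-noised world position (sigma = 1.5 m) -- the
training table for the coordinate regressors.
"""

import numpy as np

from goatloc import generate_coord_dataset, near_field_scenario

cams, traj = near_field_scenario(n_frames=5, seed=0, image_size=96)
ds = generate_coord_dataset(cams, traj, gps_noise_std=1.5, seed=1)

print("Num  xmin   ymin   xmax   ymax   Pan     Tilt   Zoom  Xw       Zw")
for r in ds.records[:8]:
    xw = "--" if r.xw is None else f"{r.xw:8.3f}"
    zw = "--" if r.zw is None else f"{r.zw:8.3f}"
    print(f"{r.num:<4d} {r.xmin:6.2f} {r.ymin:6.2f} {r.xmax:6.2f} {r.ymax:6.2f} "
          f"{r.pan:7.2f} {r.tilt:6.2f} {r.zoom:5.2f} {xw} {zw}")

resid = np.array([[r.xw, r.zw] for r in ds.records if r.complete]) \
    - ds.truth[[r.complete for r in ds.records]]
print(f"\n{len(ds.records)} records from 5 frames; "
      f"GPS residual std so far: {resid.std(ddof=1):.2f} m (sigma = 1.5 m)")
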