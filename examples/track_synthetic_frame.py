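"""Render a synthetic dark-field frame and recover the fish pose.

A virtual larva at a known pose is drawn as overlapping Gaussian blobs
on a noisy dark background, then the tracker estimates head, center,
tail and heading from the image alone.  Errors are reported in pixels
and degrees.
"""

import numpy as np

from larvalearn import render_fish, track_frame
from larvalearn.session import TrackPoint, wrap_angle_deg

true = TrackPoint(
    t=0.0,
    head=(1.7, 1.6), center=(1.5, 1.5), tail=(1.3, 1.4),
    heading=float(np.degrees(np.arctan2(0.2, 0.2))),
)

frame = render_fish(true, rng=np.random.default_rng(3), noise_sd=0.01)
est = track_frame(frame)

err_px = np.hypot(est.center[0] - true.center[0],
                  est.center[1] - true.center[1]) / frame.scale
err_deg = abs(float(wrap_angle_deg(est.heading - true.heading)))

print(f"true  center ({true.center[0]:.3f}, {true.center[1]:.3f}) cm, "
      f"heading {true.heading:7.2f} deg")
print(f"est.  center ({est.center[0]:.3f}, {est.center[1]:.3f}) cm, "
      f"heading {est.heading:7.2f} deg")
print(f"center error {err_px:.2f} px; heading error {err_deg:.2f} deg")
print("\n-> the moment-based tracker recovers the pose to sub-pixel /")
print("   few-degree accuracy, adequate for >15 deg turn-event detection.")
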