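"""Segment a movement path into extensive and intensive modes, and show
how sampling resolution biases the classification.

A two-mode correlated random walk (extensive = short, high-turning
steps; intensive = long, straight steps) is sampled at its native
5-min resolution and again at hourly GPS resolution.  K-means on
(log step length, turning angle) recovers the generating modes at fine
resolution; at hourly resolution the same path is classified
substantially more often as intensive, because subsampling straightens
the apparent track.
"""

import numpy as np
import pandas as pd

from terrapath import paths, synth

cfg = synth.SynthConfig(seed=2, days=10)

for label, interval in (("5-min (thread-like)", None),
                        ("hourly (GPS-like)", pd.Timedelta(hours=1))):
    parts = []
    for i in range(6):
        fine, _ = synth.simulate_track(
            cfg, f"T{i:02d}", rng=np.random.default_rng(100 + i)
        )
        pts = fine[["individual", "timestamp", "x", "y"]]
        if interval is not None:
            pts = paths.subsample(pts, interval)
        parts.append(paths.compute_steps(pts.reset_index(drop=True)))
    steps = pd.concat(parts, ignore_index=True)
    labelled, s = paths.classify_modes(steps, seed=0)
    frac_int = s.n_intensive / (s.n_intensive + s.n_extensive)
    print(f"{label:>22}: {s.n_extensive:5d} extensive / {s.n_intensive:5d} "
          f"intensive ({frac_int:.0%} intensive); mean turn angle "
          f"{s.mean_angle_extensive:.0f} deg (ext) vs "
          f"{s.mean_angle_intensive:.0f} deg (int)")

print()
print("The intensive share rises at coarse resolution while measured")
print("turning angles fall - the direction of bias a field comparison of")
print("thread trailing vs hourly GPS shows, so the sampling scheme itself")
print("shapes the behavioural interpretation.")
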