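"""Segment one synthetic frame: threshold, watershed, prune, measure.

Draws a soil-textured crop with a disk rosette plus a few speckle-noise
blobs, then runs the detection chain and prints what survives.
"""

import numpy as np

from rosettrack import (
    binarize,
    blue_weight,
    filter_noon,
    label_objects,
    merge_and_measure,
    prune_noise,
    threshold_noon,
)

rng = np.random.default_rng(0)
h = w = 160
img = np.empty((h, w, 3))
img[:] = (0.52, 0.60, 0.46)                      # soil: G ~ R
img += rng.normal(0, 0.01, (h, w, 1))
speckle = rng.random((h, w)) < 0.05
img[speckle] = (0.92, 0.96, 0.88)                # bright perlite grains
yy, xx = np.ogrid[:h, :w]
rosette = (yy - 80) ** 2 + (xx - 80) ** 2 <= 35 ** 2
img[rosette] = (0.20, 0.55, 0.16)                # the plant
img[(yy - 20) ** 2 + (xx - 140) ** 2 <= 2 ** 2] = (0.25, 0.55, 0.20)  # a green fleck

prev_area = 1000.0                               # day-one prior
d = blue_weight(prev_area)
f = filter_noon(img, d)
t = threshold_noon(float(f.mean()), prev_area)
print(f"D = {d:.3f}, U = {f.mean():.3f}, threshold T = {t:.3f}")

objects = label_objects(binarize(f, t))
kept, removed = prune_noise(objects, prev_area)
print(f"{len(objects)} candidate objects; kept {len(kept)}, "
      f"removed {len(removed)} as noise (too small/thin)")

result = merge_and_measure(kept, f.shape, threshold=t)
true_area = int(rosette.sum())
print(f"rosette area RA = {result.area} px (truth {true_area}, "
      f"error {abs(result.area - true_area) / true_area:.1%})")
print(f"radius = {result.radius:.1f} px, "
      f"compactness = {result.area / (np.pi * result.radius ** 2):.3f}")
# A filled disk has compactness near 1; real rosettes sit well below.
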