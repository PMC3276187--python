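"""The size-weighted color filter and the dynamic background threshold.

Builds a single synthetic pixel scene and walks through the two filter
variants and the two threshold models at characteristic operating points.
"""

import numpy as np

from rosettrack import (
    blue_weight,
    filter_intraday,
    filter_noon,
    threshold_intraday,
    threshold_noon,
)

# A small plant: yesterday's rosette covered 1,000 px, so the blue-channel
# correction is nearly at full strength (pot edges still matter).
d_small = blue_weight(1000)
d_large = blue_weight(40_000)
print(f"blue-mixture weight D: small plant {d_small:.3f}, large plant {d_large:.3f}")

# One plant pixel and one blue pot-edge pixel (R, G, B on [0, 1])
plant = np.array([[[0.20, 0.55, 0.16]]])
pot_edge = np.array([[[0.25, 0.35, 0.75]]])
for name, px in [("plant", plant), ("pot edge", pot_edge)]:
    f0 = filter_noon(px, 0.0)[0, 0]
    f1 = filter_noon(px, d_small)[0, 0]
    print(f"noon filter on {name}: D=0 -> {f0:.3f}, D={d_small:.2f} -> {f1:.3f}")
# The blue mixture pushes pot-edge pixels down while barely touching plants.

# Thresholds react to the scene's mean filtered intensity U (light level)
# and to the plant's area (growth-dependent reflectance).
print(f"noon threshold, dim scene, tiny plant: "
      f"{threshold_noon(U=0.08, prev_area=1000):.4f}")
print(f"noon threshold, bright scene, big plant: "
      f"{threshold_noon(U=0.15, prev_area=30_000):.4f}")
print(f"intra-day threshold (spring, U=0.5, A=20k px): "
      f"{threshold_intraday(0.5, 20_000, 'spring'):.4f}")
print(f"intra-day threshold (summer, same scene): "
      f"{threshold_intraday(0.5, 20_000, 'summer'):.4f}")
# Foreground = filtered intensity >= threshold; the threshold slides with
# light and growth so one parameter set covers the whole time series.
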