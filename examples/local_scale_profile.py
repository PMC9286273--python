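"""Per-point local 3D scale along a single curve.

A curve that starts as a straight line and ends in a 3D tangle should
have a low local 3D scale on the straight part (its 3D structure, if
any, is tiny) and a high one in the tangle (3D structure persists up to
large scales).
"""

import numpy as np

from nadder import curve_local_3d_scale, resample_curve, simulate_composite

rng = np.random.default_rng(3)
sim = simulate_composite(dims=[1, 3], sigma=0.0, rng=rng)
curve = resample_curve(sim.curve, 1.0)

profile = curve_local_3d_scale(curve, max_scale=60.0, n_scales=12)

half = curve.n_points // 2
print(f"median local 3D scale, first (straight) half : "
      f"{np.median(profile.values[:half]):5.1f} um")
print(f"median local 3D scale, second (3D) half      : "
      f"{np.median(profile.values[half:]):5.1f} um")
print("the metric reads as: below this size (in um), the curve around"
      " the point looks one- or two-dimensional.")
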