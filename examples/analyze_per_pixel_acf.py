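"""Per-pixel ACF analysis of a simulated movie: recover blinking kinetics.

Every ring pixel's intensity series is autocorrelated, classified as
decaying (spot-exit dominated) or growing (spot-entry dominated), and fit
with the constrained single exponential A*exp(-Gamma*t) + y.  The median
accepted decay constant estimates the spots' rate sum k_on + k_off.
"""

import numpy as np

from dxblink import RingGeometry, SimulationConfig, simulate_movie
from dxblink.blinking_acf import analyze_stack
from dxblink.ensemble_stats import DecayEnsemble, summarize

config = SimulationConfig(n_spots=76, k_on=0.3, k_off=0.3, n_frames=2000, seed=7)
ring = RingGeometry(shape=(100, 100), center=(50, 50), radius=40, halfwidth=0.5)
stack, truth = simulate_movie(config, ring)

rows, cols = np.mgrid[0:100, 0:100]
radius = np.hypot(rows - 50, cols - 50)
pixels = np.argwhere((radius >= 38.5) & (radius <= 41.5))  # annulus around the ring

table = analyze_stack(stack, None, None, pixels=pixels)
ensemble = DecayEnsemble.from_table(table, condition="demo")
stats = summarize(ensemble)

print(f"{len(pixels)} ring pixels analyzed, {stats['n_accepted']} accepted, "
      f"{stats['n_rejected']} rejected")
accepted = table[table["accepted"]]
print("direction split:", accepted["direction"].value_counts().to_dict())
print(f"median Gamma = {stats['median_gamma']:.3f} /s "
      f"(ground truth {config.rate_sum:.2f} /s)")
print(f"Lorentz mode = {stats['lorentz_mode']:.3f} /s, IQR = {stats['iqr']:.3f}")
# The median and mode agree with the simulated rate sum to within the
# per-pixel estimator spread; rejected pixels are background or poor fits.
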