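"""Carrying-capacity calibration of the competitive weight k_c.

For each species preset, finds the Beverton-Holt competitive weight that
holds a single perfectly adapted patch at its nominal maximum adult
number, then confirms the stochastic simulator fluctuates around the
deterministic fixed point.
"""

import numpy as np

from evorange.demography import SPECIES_PRESETS, deterministic_equilibrium, \
    simulate_patch_counts
from evorange.regulation import calibrate_kc

rng = np.random.default_rng(2)
print(f"{'species':<10} {'K_max':>6} {'k_c':>9} {'determ. N*':>10} "
      f"{'stochastic N* (last 200y)':>26}")
for name, sp in SPECIES_PRESETS.items():
    k_c = calibrate_kc(sp)
    det = deterministic_equilibrium(sp, k_c)["adults"]
    res = simulate_patch_counts(sp, k_c, 500, rng)
    stoch = res["adults"][-200:].mean()
    print(f"{name:<10} {sp.K_max:>6} {k_c:>9.4f} {det:>10.1f} {stoch:>26.1f}")
print("\nThe stochastic mean sits within demographic noise of the")
print("deterministic equilibrium; realized numbers in full spatial runs")
print("are lower because selection and migration loads cut recruitment.")
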