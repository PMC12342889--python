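"""Decompose a bivalent-analyte sensorgram set into kinetic modes.

A tandem-domain analyte that can bridge two surface RNAs produces biphasic
dissociation: a fast monovalent pool and a slow, avidity-stabilised bivalent
pool.  The rate-distribution map (regularised nonnegative decomposition onto
a grid of 1:1 components) separates the two as distinct (ka, kd) peaks.
"""

import numpy as np

from rrmbindkit.kinetics import (
    BivalentParams,
    InjectionSchedule,
    instantaneous_off_rate,
    interaction_map,
    simulate_bivalent,
)

schedule = InjectionSchedule((1.5625e-8, 6.25e-8, 2.5e-7), dt=1.0)
params = BivalentParams(ka1=3e6, kd1=0.1, ka2=1e-3, kd2=2e-3, Ltot=150.0)
grams = simulate_bivalent(params, schedule)

off = instantaneous_off_rate(grams[-1])
print(f"instantaneous off-rate over the wash: starts at {off[0]:.3g} s-1, "
      f"ends at {off[-1]:.3g} s-1")
print(f"monotonically nonincreasing: {bool(np.all(np.diff(off) <= 1e-6))} "
      "(the biphasic fingerprint)")

grid = interaction_map(grams, lam=1e-3)
print(f"\nrate-distribution map: {len(grid.peaks)} peaks")
for (ka, kd), (i, j) in zip(grid.peak_rates(), grid.peaks):
    print(f"  ka ~ {ka:.3g} M-1 s-1, kd ~ {kd:.3g} s-1 "
          f"(weight {grid.weights[i, j]:.1f} RU)")

print("\nThe fast-kd peak is the monovalent interaction; the slow-kd peak is")
print("the bridged, avidity-stabilised pool that dominates late dissociation.")
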