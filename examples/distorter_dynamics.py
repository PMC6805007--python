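"""Equilibria of a feminizing cytoplasmic distorter in an XY/XX population.

Sweeps the maternal transmission rate alpha with YY mothers blocked from
transmitting (t_Y = 0), then contrasts the invasion thresholds of the
blocked and uniform parameterizations.
"""

import numpy as np

from wolbsex import TransmissionRates, invasion_threshold, iterate_to_equilibrium, \
    perturbed_start, sweep_alpha

# one run below threshold: the distorter dies out and the standard
# population (XY males / XX females) returns, i.e. X at 75% of copies
res = iterate_to_equilibrium(perturbed_start(0.01), TransmissionRates.from_alpha(0.4, "blocked"))
print(f"alpha=0.4 blocked: X={res.x_freq:.3f} Y={res.y_freq:.3f} "
      f"distorter={res.distorter_freq:.3f} lost={res.distorter_lost}")

table = sweep_alpha("blocked", np.arange(0, 1.0001, 0.05))
print(f"blocked sweep:   min X frequency      = {table.x_freq.min():.4f}  (never below 1/8)")
print(f"blocked sweep:   max distorter freq   = {table.distorter_freq.max():.4f}  (never above 1/2)")
print(f"blocked sweep:   female freq range    = "
      f"[{table.female_freq.min():.4f}, {table.female_freq.max():.4f}]  (sex ratio stays balanced)")

for mode in ("uniform", "blocked"):
    thr, _ = invasion_threshold(mode)
    print(f"{mode:8s} invasion threshold alpha* = {thr:.6f}")
# Above alpha* the distorter spreads from rarity; blocking YY transmission
# raises the threshold from 1/2 to 2 - sqrt(2) and caps the distorter at 50%.
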