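"""Generate a synthetic contact map and inspect its structure.

Builds a 200-bin map with power-law contact decay and three TAD-like blocks,
extracts the prominent contacts, and checks the decay exponent by regression
on the P(s) curve.
"""

import numpy as np

import chromocg as cc

spec = cc.SyntheticMapSpec(
    n_bins=200, decay_exponent=1.0, amplitude=0.9,
    tad_boundaries=(70, 130), tad_boost=3.0, noise_cv=0.2, seed=7,
)
cmap = cc.generate_synthetic_map(spec)
prom = cc.find_prominent_contacts(cmap)

# the decay exponent is cleanly read off a map without TAD enrichment
plain = cc.generate_synthetic_map(cc.SyntheticMapSpec(
    n_bins=200, decay_exponent=1.0, amplitude=0.5, seed=7))
curve = cc.contact_probability_curve(plain)
s, p = curve[2:100, 0], curve[2:100, 1]
slope = np.polyfit(np.log(s), np.log(p), 1)[0]

print(f"bins: {cmap.n_bins}, resolution: {cmap.resolution_bp} bp")
print(f"prominent contacts: {len(prom)} "
      f"(pairs at least 1 SD above their |i-j| stratum mean)")
print(f"P(s) log-log slope (TAD-free map): {slope:.3f}  "
      f"(generator decay exponent: -1.0)")
# The slope recovers -gamma; in the TAD map the prominent-contact set is
# dominated by the boosted blocks, which is what step-1 bonding will anchor.
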