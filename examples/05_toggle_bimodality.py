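"""Bistability of the genetic toggle switch seen as a bimodal snapshot.

Simulates flow-cytometry-like endpoint data of the toggle switch at
IPTG 6e-5 M and prints the histogram of the GFP-proxy repressor count.
Two well-separated modes — cells latched in opposite states — should be
visible, the hallmark the CDF-distance criterion has to fit.
"""

import numpy as np

import cmefit as cf

dataset = cf.generate_case_study("toggle_switch", m=4000, seed=13)
v = dataset.observations["V"][:, -1]

print(f"{v.size} cells at t = {dataset.sample_times[-1]:g}")
hist = np.bincount(v, minlength=25)
for count in range(25):
    bar = "#" * int(60 * hist[count] / hist.max())
    print(f"{count:3d} | {bar}")
low, high = (v <= 3).mean(), (v >= 8).mean()
print(f"\nfraction in low mode (<=3): {low:.2f}, high mode (>=8): {high:.2f}")
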