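"""Compare objective-surface steepness of the three estimation criteria.

Scans the normalized DFD-CDF, DFD-PDF and ML objectives of the E. coli
mRNA model along the transcription rate k2 (other rates fixed at truth)
and prints the surfaces side by side.  The CDF criterion rises fastest
away from the optimum — the steeper surface behind its faster DE
convergence.
"""

import numpy as np

import cmefit as cf

dataset = cf.generate_case_study("ecoli_rna", m=10_000, seed=31)
net = cf.builtin_model("ecoli_rna")
k2_grid = np.linspace(0.05, 0.45, 9)

surfaces = {}
for method in ["dfd_cdf", "dfd_pdf", "ml"]:
    spec = cf.ObjectiveSpec(method=method, n_ssa_realizations=1000)
    _, _, surf = cf.scan_objective(net, dataset, spec, {"k2": k2_grid}, rng=3)
    surfaces[method] = surf

print(f"{'k2':>6} | {'DFD-CDF':>10} {'DFD-PDF':>10} {'ML':>10}   (objective / minimum)")
for i, k2 in enumerate(k2_grid):
    row = " ".join(f"{surfaces[m][i]:10.3f}" for m in ["dfd_cdf", "dfd_pdf", "ml"])
    print(f"{k2:6.3f} | {row}")
print("\ntrue k2 = 0.17; a value of 1.000 marks each criterion's minimum")
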