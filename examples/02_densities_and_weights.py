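"""Histogram densities with adaptive binning and finite-sampling weights.

Draws a Poisson-like molecular-count sample, bins it under the
"at least ten occurrences per bin" rule, and prints each bin with its
probability and binomial sampling variance p(1-p)/N — the inverse
weights the distance criteria use.  Also shows the order-statistic ECDF
used for sparse (few-replicate) data.
"""

import numpy as np

import cmefit as cf

rng = np.random.default_rng(0)
samples = rng.poisson(4.0, size=300)

scheme = cf.build_bins(samples, min_count=10)
pdf = cf.pdf_from_samples(samples, scheme)
print(f"{scheme.n_bins} bins over [{scheme.edges[0]:g}, {scheme.edges[-1]:g}]")
print(pdf.to_frame().to_string(index=False))

cdf = cf.cdf_from_pdf(pdf)
print("\ncumulative probabilities:", np.round(cdf.probs, 3))

replicates = rng.poisson(4.0, size=10)
ecdf = cf.sparse_ecdf(replicates)
print("\nsparse ECDF (m = 10 replicates):")
for v, p in zip(ecdf.values, ecdf.positions):
    print(f"  count {v:2d}  ->  F = {p:.2f}")
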