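"""Probability filtering and FDR estimation on calibrated synthetic scores.

Generates 10,000 identifications with calibrated posterior probabilities,
accepts those with probability >= 0.97, and compares the posterior-based
FDR estimate mean(1-p) with the realized false fraction.
"""

import numpy as np

from matricount import estimate_fdr, simulate_confidences

rng = np.random.default_rng(1)
p, correct = simulate_confidences(10_000, rng)

threshold = 0.97
accepted = p >= threshold
est = estimate_fdr(p[accepted])
empirical = 1.0 - correct[accepted].mean()

print(f"accepted {accepted.sum()} of {p.size} identifications at p >= {threshold}")
print(f"estimated FDR (mean 1-p):  {est:.4f}")
print(f"realized false fraction:   {empirical:.4f}")
print("-> on calibrated scores the two agree; a 0.97 threshold yields an")
print("   accepted set whose FDR is in the few-per-thousand range.")
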