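"""2^-ddCt relative quantification of a planted 10.8-fold transcript change.

Simulates actin-normalized Ct values (0.3-cycle noise, n=5 per group) and
recovers the group fold change with a Welch t-test.
"""

import numpy as np

from matricount import GeneratorConfig, group_fold_change, simulate_qpcr

cfg = GeneratorConfig(n_genes=1, planted_folds={"g00": 10.8}, seed=2)
records, truth = simulate_qpcr(cfg, ["g00"], np.random.default_rng(cfg.seed))

print("dCt values (target Ct - reference Ct) per well:")
for r in records:
    print(f"  {r.sample_id:<10} {r.group:<9} dCt = {r.ct_target - r.ct_reference:6.3f}")

res = group_fold_change(records, "g00", "tumor", "control")
print(f"\nplanted tumor/control fold: {truth['qpcr_folds']['g00']['tumor']}")
print(f"recovered fold (geometric mean 2^-ddCt): {res.fold:.2f}  p = {res.p_value:.2g}")
print("-> a 10.8x change is a ~3.4-cycle dCt shift, far above 0.3-cycle noise.")
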