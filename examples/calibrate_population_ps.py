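"""Calibrate a population permeability-surface area product.

Builds paired (MRI K1, PET MBF) observations across rest and stress flows,
adds 5% measurement noise, and fits the single Renkin-Crone PS that best
explains the pairs — the procedure that ties a K1-only MRI analysis to an
absolute flow scale.
"""

import numpy as np

from dualflow import calibrate_population_ps, renkin_crone_k1

PS_TRUE = 2.6  # mL/g/min
rng = np.random.default_rng(3)

flows = rng.uniform(0.5, 4.0, 24)          # 12 subjects x rest/stress
k1 = np.array([renkin_crone_k1(f, PS_TRUE) for f in flows])
pairs = list(zip(k1 * (1 + 0.05 * rng.standard_normal(24)),
                 flows * (1 + 0.05 * rng.standard_normal(24))))

ps_hat = calibrate_population_ps(pairs)
print(f"generating PS = {PS_TRUE} mL/g/min")
print(f"calibrated PS = {ps_hat:.3f} mL/g/min from {len(pairs)} noisy pairs")
print("\nThe estimate leans on the high-flow pairs, where K1 saturates "
      "towards PS; a\ncohort spanning rest and stress flows is what makes "
      "the single-parameter fit\nwell-conditioned.")
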