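"""Renkin-Crone extraction: why gadolinium K1 underestimates flow.

Evaluates the extraction fraction E = 1 - exp(-PS/F) and influx constant
K1 = E*F of Gd-DOTA (PS ~ 2.6 mL/g/min) across the physiological flow range,
then inverts the relation and shows how the correction amplifies noise at
stress flows.
"""

from dualflow import (
    renkin_crone_extraction,
    renkin_crone_invert,
    renkin_crone_k1,
)
from dualflow.kinetics import extraction_correction_amplification

PS = 2.6  # Gd-DOTA permeability-surface area product, mL/g/min

print(f"Gd-DOTA, PS = {PS} mL/g/min")
print(f"{'F':>5} {'E':>6} {'K1':>6} {'dF/dK1':>7}")
for F in (0.5, 1.0, 2.0, 3.0, 4.0):
    E = renkin_crone_extraction(F, PS)
    K1 = renkin_crone_k1(F, PS)
    amp = extraction_correction_amplification(F, PS)
    print(f"{F:5.1f} {E:6.3f} {K1:6.3f} {amp:7.2f}")

K1_measured = 1.70
F_corrected = renkin_crone_invert(K1_measured, PS)
print(f"\nExtraction-corrected flow for measured K1 = {K1_measured}: "
      f"F = {F_corrected:.3f} mL/g/min")
print("At rest (F ~ 1) extraction is near-complete and K1 tracks flow; at "
      "stress (F ~ 3-4)\nextraction drops below 0.6, K1 saturates towards "
      "PS, and the inverse map multiplies\nmeasurement noise several-fold — "
      "the instability of the corrected route.")
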