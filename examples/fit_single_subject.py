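"""Fit one synthetic subject with all four analysis routes.

Simulates one rest/stress subject (6-min water-PET scan and 65-beat DCE-MRI
scan at realistic noise), then estimates myocardial blood flow with the PET
water model and the three MRI routes, printing estimates next to the
generating truth.
"""

from dualflow import (
    CohortConfig,
    fit_gd_1tcm_ps,
    fit_gd_ef_corrected,
    fit_gd_plain_1tcm,
    fit_water_1tcm,
    sample_ground_truth,
    signal_to_concentration,
    simulate_mri_scan,
    simulate_pet_scan,
)
from dualflow.cohort import BLOOD_SIGNAL, TISSUE_SIGNAL

config = CohortConfig(n_subjects=2, seed=14, segment_heterogeneity_cv=0.0)
truth = sample_ground_truth(config)
subject = truth.subjects[0]
print(f"{subject.subject_id}: true PS = {subject.PS:.2f} mL/g/min")

for condition in ("rest", "stress"):
    F_true = subject.F_global[condition]
    pet = simulate_pet_scan(truth, subject, condition)
    r_pet = fit_water_1tcm(pet.global_tac, pet.aif)

    mri = simulate_mri_scan(truth, subject, condition)
    conc = signal_to_concentration(mri.global_signal, TISSUE_SIGNAL)
    aif = signal_to_concentration(mri.blood_signal, BLOOD_SIGNAL)
    plain = fit_gd_plain_1tcm(conc, aif)
    ef = fit_gd_ef_corrected(conc, aif, ps_population=2.6)
    direct = fit_gd_1tcm_ps(conc, aif)

    print(f"\n{condition}: true MBF = {F_true:.2f} mL/g/min")
    print(f"  PET water 1TCM        F  = {r_pet.F:.2f}")
    print(f"  MRI plain 1TCM        K1 = {plain.params.K1:.2f}")
    print(f"  MRI extraction-corr.  F  = {ef.params.F:.2f} "
          f"(error amplification x{ef.amplification:.1f})")
    print(f"  MRI 1TCM+PS direct    F  = {direct.params.F:.2f}, "
          f"PS = {direct.params.PS:.2f}")

print("\nThe plain-model K1 sits well below true flow at stress (low Gd "
      "extraction); the\ndirect PS-embedded fit recovers flow on both "
      "conditions and estimates PS itself.")
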