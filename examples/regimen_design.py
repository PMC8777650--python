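"""Design the minimal sustained-release regimen for repurposed sobrerol.

Converts the animal doses to human equivalent doses, derives the minimum
effective concentration from the highest no-effect dose, simulates the
reference immediate-release regimen, and searches for the smallest
twice-daily sustained-release dose that preserves the duration of action.
"""

from pelletpk import (
    Regimen,
    compliance_summary,
    determine_mec,
    hed,
    ka_from_kd,
    min_dose_for_efficacy,
    profile_metrics,
    simulate_regimen,
)
from pelletpk.design import HEDSpec
from pelletpk.datasets import SOBREROL_PK_PARAMS
from pelletpk.ivivc import SOBREROL_KA_KD_LINK

params = SOBREROL_PK_PARAMS

hed_best = hed(HEDSpec(animal_dose=100.0, frequency_per_day=3))
hed_noeffect = hed(HEDSpec(animal_dose=30.0, frequency_per_day=1))
print(f"HED of the effective regimen: {hed_best:.0f} mg thrice daily "
      f"({3 * hed_best:.0f} mg/day)")
print(f"HED of the highest no-effect dose: {hed_noeffect:.0f} mg once daily")

mec = determine_mec(params, hed_noeffect)
print(f"MEC (peak of the {hed_noeffect:.0f} mg single dose): {mec:.2f} ug/mL")

reference = Regimen(dose=486.0, dose_times=(0.0, 8.0, 16.0))
ref_metrics = profile_metrics(simulate_regimen(params, reference), mec)
print(f"Reference 486 mg TID: t>MEC = {ref_metrics.t_gt_mec:.1f} h over 24 h")

kd = 0.65  # target dissolution constant of the sustained-release pellets
dose = min_dose_for_efficacy(
    params, SOBREROL_KA_KD_LINK, mec, kd=kd, frequency=2,
    target_t=ref_metrics.t_gt_mec,
)
designed = Regimen(dose=dose, dose_times=(0.0, 12.0))
sr_params = params.with_ka(ka_from_kd(kd, SOBREROL_KA_KD_LINK))
sr_metrics = profile_metrics(simulate_regimen(sr_params, designed), mec)
print(f"Minimal SR dose at kd = {kd} /h: {dose:.0f} mg twice daily "
      f"(t>MEC = {sr_metrics.t_gt_mec:.1f} h)")

freq_red, dose_red = compliance_summary(reference, designed)
print(f"Vs the reference: {freq_red:.1f}% fewer administrations and "
      f"{dose_red:.1f}% lower daily dose at equal-or-better duration of action.")
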