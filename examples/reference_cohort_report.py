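"""Recompute the reference cohort's descriptive statistics and the
fMRI-versus-stimulation sensitivities from the bundled fixtures.

Loads the shipped cohort, laterality and concordance tables (transcribed
from a published 50-patient awake-craniotomy series), and prints the
quantities the pipeline is checked against: the 65.6% task-fMRI and 100%
resting-state sensitivities for intraoperative stimulation sites, the
demographic summary, and the left-handed subgroup's dominance counts.
"""

from langmap import (
    compare_to_reference,
    load_cohort,
    load_laterality_table,
    load_reference_concordance,
    sensitivity,
    summarize,
)
from langmap.cohort import left_hander_summary

records = load_reference_concordance()
for modality in ("task", "rest"):
    rep = sensitivity(records, modality)
    print(f"{modality:>4} fMRI sensitivity: {rep.n_detected}/{rep.n_cm_positive} "
          f"= {rep.sensitivity}% of stimulation-positive patients")

cohort = load_cohort()
s = summarize(cohort)
print(f"\ncohort: n = {s['n']} ({s['n_male']} M / {s['n_female']} F), "
      f"age {s['mean_age']:.1f} +/- {s['sd_age']:.1f} y")
print(f"anxiety {s['mean_anxiety']:.1f} +/- {s['sd_anxiety']:.1f}, "
      f"success {s['mean_success']:.1f} +/- {s['sd_success']:.1f} (0-10 scale)")
print(f"histology: {s['n_glial']} glial, {s['n_metastasis']} metastases, "
      f"{s['n_nontumoral']} nontumoral; "
      f"{s['n_language_disturbance']} patients with a language disturbance")

anx = compare_to_reference(cohort["anxiety"], 1.7, 1.3, 33)
print(f"anxiety vs healthy volunteers (1.7 +/- 1.3, n 33): "
      f"t = {anx['t']:.1f}, p = {anx['p']:.2e} ({anx['direction']})")

hands = left_hander_summary(load_laterality_table())
print(f"\nleft-handers: {hands['n_left_handed']}, mean Edinburgh "
      f"{hands['mean_edinburgh_unit']:.2f}; right-dominant at rest: "
      f"{hands['n_right_dominant_rest']}/{hands['n_left_handed']} "
      f"(positive LI = right-hemisphere dominance)")
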