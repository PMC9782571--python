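"""Screen a synthetic consenting cohort and print the disposition flow.

Builds a 2490-subject roster carrying known rule violations (4 under-age,
12 repeat enrollments, 156 unconfirmed diagnoses, 18 failed sample-quality
checks), applies every inclusion/exclusion rule, and prints the patient-flow
accounting: how many were excluded per reason and how many remain eligible
per group.
"""

from metaboflow import SimulationConfig, disposition
from metaboflow.simulate import simulate_roster

cfg = SimulationConfig(
    n_subjects=2490, seed=0,
    violations={"age_under_18": 4, "repeat_enrollment": 12,
                "unconfirmed_diagnosis": 156, "failed_sample_quality": 18})
disp = disposition(simulate_roster(cfg))

print(f"consenting subjects : {disp.n_consenting}")
print(f"excluded            : {disp.n_excluded}")
for reason, count in sorted(disp.exclusion_counts.items()):
    print(f"  {reason:<24s} {count}")
print(f"eligible            : {disp.n_eligible}")
print("eligible per group  :", dict(sorted(disp.group_counts.items())))
print("\nEach excluded subject is tabulated under its first canonical "
      "reason; eligible = consenting - excluded.")
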