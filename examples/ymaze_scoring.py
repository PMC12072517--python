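"""Score simulated Y-maze retrieval trials.

Three cohorts with different probabilities of entering the previously blocked
(novel) arm first; the forced-alternation percentage is the fraction of mice
whose first retrieval entry is the novel arm.
"""

from oxprofile import cohort_table, forced_alternation, generate_ymaze_cohort

cohorts = {
    "WT": generate_ymaze_cohort(15, 14 / 15, seed=1, group="WT"),
    "5xFAD": generate_ymaze_cohort(15, 9 / 15, seed=2, group="5xFAD"),
    "5xFAD+NAC": generate_ymaze_cohort(15, 14 / 15, seed=3, group="5xFAD+NAC"),
}

for group, sessions in cohorts.items():
    print(f"{group}: forced alternation {forced_alternation(sessions):.0f}%")

table = cohort_table([s for ss in cohorts.values() for s in ss])
print("\nPer-arm entry and dwell percentages (mean +/- SEM over mice):")
print(table.round(1).to_string())
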