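"""Simulate the default three-group familial-risk cohort and summarise it.

The generator reproduces the study design exactly: 93/74/35 participants
at baseline (controls who remained well, high-risk well, high-risk who
developed a mood disorder) and 46/47/31 at the ~2-year follow-up, with
family nesting inside the high-risk groups and HRSD depression scores
that run higher in the HR-MD group.
"""

from padtrack import SimulationConfig, attrition_report, demographics_table, simulate_cohort

config = SimulationConfig(seed=1)
cohort = simulate_cohort(config)

print("participants:", len(cohort))
print(demographics_table(cohort).to_string(index=False))

report = attrition_report(cohort)
print("\nattrition (percent lost between baseline and follow-up):")
for group, pct in report.attrition_percent.items():
    print(f"  {group:8s} {pct:5.1f}%")
print("\npairwise Yates chi-squares (differential attrition):")
print(report.pairwise.to_string(index=False))
# HR-MD retains far more participants than the well groups, exactly as the
# design's follow-up counts dictate; chi-square values quantify that gap.
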