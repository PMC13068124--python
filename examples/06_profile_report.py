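"""Render a decision-support-style profile report for one subject.

A fitted k-modes model assigns the subject to its nearest prototype; the
report lists the run's consensus drivers split into genetic vs modifiable
factors, maps them to intervention categories, and carries an explicit
non-diagnostic disclaimer.
"""

from dataclasses import replace

from dermaprofile import (
    HyperParams,
    assign_profile,
    fit_kmodes,
    generate_cohort,
    render_report,
)
from dermaprofile.synthetic import preset

cohort, _ = generate_cohort(replace(preset("separable4"), n_subjects=500, seed=3))
model = fit_kmodes(
    cohort.to_array(), HyperParams(4, "Huang", 10, 100), seed=0,
    feature_names=cohort.feature_names,
)

# drivers would normally come from a nested-cv run's consensus set
consensus = ["Low.H2O", "Stress", "GPX", "MMP-3", "Is_Winter", "Menopause"]
subject = cohort.subjects[0]
report = assign_profile(
    model, subject, cohort.data.loc[subject].to_dict(), consensus, cohort
)
print(render_report(report, "text"))
print(render_report(report, "json"))
# The mismatch count says how many of the 32 categorical features differ
# from the assigned cluster's prototype — a rough typicality measure.
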