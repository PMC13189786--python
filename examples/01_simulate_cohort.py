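"""Generate a synthetic study-emulation cohort and inspect its composition.

The generator draws two latent sonographic patterns (50.5% / 49.5%), 23
categorical ultrasound features conditionally independent given the pattern,
clinical covariates, and a rare non-response outcome (~4.3% marginal rate,
pattern odds ratio 2.5). 48 cases are tagged as Miller-Payne-assessed, 2 of
them non-responders.
"""

from sonopattern import generate_cohort, paper_emulation_config

config = paper_emulation_config()
cohort = generate_cohort(config, seed=1, exact_n_events=22)

print("cohort QC:", cohort.qc_report())
print("\ntrue pattern shares:", cohort.data["true_class"].value_counts(normalize=True).round(3).to_dict())
print("events among MP-assessed:", int(cohort.outcome[cohort.data.assessment_system == "MP"].sum()))
# The QC block reports 509 patients, 22 non-responders (4.32%), and the
# 461/48 RCB/MP split the sensitivity analysis relies on.
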