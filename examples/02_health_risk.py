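"""Deterministic health risk: doses, hazard quotients, cancer risk.

Evaluates the three exposure routes (oral ingestion, dermal contact,
inhalation of resuspended dust) for adults, teenagers and children on a
synthetic survey, then summarises which site/metal combinations exceed the
decision thresholds (HQ or HI > 1; CR > 1e-4).
"""

import soilrisk as sr

survey = sr.generate_survey(sr.survey_design(seed=1))
profiles = sr.load_defaults("exposure")
toxicity = sr.load_defaults("toxicity")

table = sr.risk_pipeline(survey, profiles, toxicity)

unacceptable = table.records.query("cr_band == 'unacceptable'")
print(f"{len(unacceptable)} (site, metal, route, age) combinations with CR > 1e-4")
print(
    unacceptable.groupby(["metal", "route", "age_group"])
    .size().rename("n_sites").reset_index().to_string(index=False)
)

hi_over = table.hi.query("hi_exceeds")
print(f"\n{len(hi_over)} (site, route, age) hazard indices above 1, e.g.:")
print(hi_over.head(5).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nHI sums the per-metal hazard quotients within one route and age group;")
print("values above 1 flag aggregate non-carcinogenic concern at that site.")
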