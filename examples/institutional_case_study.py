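"""Before/after comparison of molecular testing inside one institute.

Generates synthetic patient cohorts with the published aggregate structure
(patient-level records are not public), summarises each period, runs the
between-period tests and annualises to an institutional budget impact.
"""

from panelcost import (
    annualize,
    compare_periods,
    institutional_budget_impact,
    load_bia_inputs,
    load_cohort_profile,
    paired_cohorts,
    summarize_period,
)

catalog = load_bia_inputs("netherlands").catalog

for indication in ("nsclc", "melanoma"):
    before, after = paired_cohorts(
        load_cohort_profile(f"{indication}_before"),
        load_cohort_profile(f"{indication}_after"),
        seed=1,
    )
    yearly, _ = annualize([*before, *after], observation_months=3.5, catalog=catalog)
    bs = summarize_period(before, catalog)
    as_ = summarize_period(after, catalog)
    impact = institutional_budget_impact(bs, as_, yearly)
    result = compare_periods(before, after, catalog)

    print(f"== {indication} (n = {bs.n_patients}/{as_.n_patients}, "
          f"{yearly} patients/year)")
    print(f"  tests/patient: {bs.tests_per_patient.mean:.2f} -> "
          f"{as_.tests_per_patient.mean:.2f} "
          f"(Mann-Whitney p = {result['tests_per_patient'].p_value:.3f})")
    print(f"  cost/patient:  EUR {bs.cost_per_patient.mean:.0f} -> "
          f"EUR {as_.cost_per_patient.mean:.0f} "
          f"(p = {result['cost_per_patient'].p_value:.3f})")
    print(f"  budget impact: EUR {impact.per_patient_rounded:+d}/patient, "
          f"EUR {impact.population_rounded:+,d}/year")
    print()

print("A positive impact means the NGS period was more expensive; the yearly")
print("figure scales the per-patient change by the annualised patient count.")
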