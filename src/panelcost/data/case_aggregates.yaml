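# Published institutional case-study aggregates (the before/after windows
# span 3.5 months in total: 2 months before and 1.5 months after the NGS
# introduction).  Population cells are yearly extrapolations.
observation_months: 3.5
cohorts:
  nsclc: {before: 47, after: 53}
  melanoma: {before: 36, after: 36}
yearly_patients:
  nsclc: 343
  melanoma: 247
period_costs:  # euros
  nsclc:
    before: {per_patient: 784.0, population: 268870.0}
    after: {per_patient: 1141.0, population: 391368.0}
  melanoma:
    before: {per_patient: 711.0, population: 175622.0}
    after: {per_patient: 698.0, population: 172211.0}
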