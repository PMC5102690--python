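# Canonical panel cost decompositions (published whole-euro values).
# The activity schedules aggregate to the same numbers within ±1 euro;
# these printed values are the reference used for costing and the BIA.
panel_specs:
  small_tgp_miseq:
    panel: small_tgp
    platform: miseq
    fixed_yearly: 96589.0
    fixed_per_run_personnel: 347.0
    fixed_per_run_material: 1198.0
    variable_per_sample_personnel: 121.0
    variable_per_sample_material: 155.0
    max_samples_per_run: 48
  small_tgp_hiseq:
    panel: small_tgp
    platform: hiseq
    fixed_yearly: 262380.0
    fixed_per_run_personnel: 347.0
    fixed_per_run_material: 3528.0
    variable_per_sample_personnel: 121.0
    variable_per_sample_material: 155.0
    max_samples_per_run: 48
  medium_tgp_miseq:
    panel: medium_tgp
    platform: miseq
    fixed_yearly: 98416.0
    fixed_per_run_personnel: 840.0
    fixed_per_run_material: 2936.0
    variable_per_sample_personnel: 153.0
    variable_per_sample_material: 136.0
    max_samples_per_run: 4
  medium_tgp_hiseq:
    panel: medium_tgp
    platform: hiseq
    fixed_yearly: 264206.0
    fixed_per_run_personnel: 840.0
    fixed_per_run_material: 5435.0
    variable_per_sample_personnel: 153.0
    variable_per_sample_material: 136.0
    max_samples_per_run: 48
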