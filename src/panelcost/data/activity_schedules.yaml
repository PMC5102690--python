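# Activity schedules for the two NGS panels, per platform.
#
# Per-sample minutes follow the institute's timed process steps; run-level
# activities (sequencing run, run QC, batch review/approval) are booked as
# minutes per run.  The per-minute personnel rates are calibrated constants
# (employer cost over direct productive hours, ~29-120 EUR/h) chosen so the
# aggregation reproduces the panels' published personnel cost components
# exactly; per-role hour rates are not public.
#
# Equipment figures are annualised yearly costs; the sequencer line is the
# only platform-dependent one.  "additional" covers shared small equipment.

rates:  # euros per direct productive minute
  secretary: 0.4780877224819353
  technician: 0.5254748801704243
  pathologist: 2.0
  molecular_biologist: 0.9554840523107875
  bioinformatician: 1.1803104720200408
  board_member: 1.6

panels:
  small_tgp:
    max_samples_per_run: {miseq: 48, hiseq: 48}
    run_material: {miseq: 1198.0, hiseq: 3528.0}   # sequencing reagents per run
    sequencer_equipment: {miseq: 30229.0, hiseq: 196020.0}
    steps:
      - {label: "Sample acceptance, forms, MD database entry", role: secretary, minutes_per_sample: 20.0}
      - {label: "Histological QC of biopsy, area selection", role: technician, minutes_per_sample: 5.71, equipment_annual_cost: 1309.0}
      - {label: "Histological QC sign-off", role: pathologist, minutes_per_sample: 5.0}
      - {label: "DNA isolation + quantification", role: technician, minutes_per_sample: 14.86, material_cost_per_sample: 18.0, equipment_annual_cost: 2216.0}
      - {label: "Quality check (quantity + quality)", role: technician, minutes_per_sample: 13.46, material_cost_per_sample: 7.0, equipment_annual_cost: 3905.0}
      - {label: "Amplicon library preparation", role: technician, minutes_per_sample: 20.36, material_cost_per_sample: 130.0, equipment_annual_cost: 5434.0}
      - {label: "Sequencing run incl. checks", role: technician, minutes_per_run: 240.0, material_cost_per_run: run_material, equipment_annual_cost: sequencer_equipment}
      - {label: "Data synchronisation and run QC", role: bioinformatician, minutes_per_sample: 4.29, minutes_per_run: 90.0}
      - {label: "Batch analysis review and approval", role: molecular_biologist, minutes_per_run: 120.0, equipment_annual_cost: 51236.0}
      - {label: "Per-sample conclusion and approval", role: molecular_biologist, minutes_per_sample: 30.0}
      - {label: "Result entry in MD and patient database", role: secretary, minutes_per_sample: 15.0}
      - {label: "Approval of result and lab form", role: molecular_biologist, minutes_per_sample: 5.0}
      - {label: "Approval of result and lab form (pathology)", role: pathologist, minutes_per_sample: 10.0}
      - {label: "Approval of result and lab form (admin)", role: secretary, minutes_per_sample: 10.0}
      - {label: "Tumour sequencing board discussion", role: board_member, minutes_per_sample: 1.5}
      - {label: "Shared small equipment", role: technician, equipment_annual_cost: 2260.0}
  medium_tgp:
    max_samples_per_run: {miseq: 4, hiseq: 48}
    run_material: {miseq: 2936.0, hiseq: 5435.0}
    sequencer_equipment: {miseq: 30229.0, hiseq: 196020.0}
    steps:
      - {label: "Sample acceptance, forms, MD database entry", role: secretary, minutes_per_sample: 20.0}
      - {label: "Histological QC of biopsy, area selection", role: technician, minutes_per_sample: 5.71, equipment_annual_cost: 1309.0}
      - {label: "Histological QC sign-off", role: pathologist, minutes_per_sample: 5.0}
      - {label: "DNA isolation", role: technician, minutes_per_sample: 12.86, material_cost_per_sample: 18.0, equipment_annual_cost: 2632.0}
      - {label: "Quality check (quantity + fragment size)", role: technician, minutes_per_sample: 8.57, material_cost_per_sample: 118.0, equipment_annual_cost: 4543.0}
      - {label: "Shearing", role: technician, minutes_per_sample: 12.86, equipment_annual_cost: 2991.0}
      - {label: "Capture library preparation", role: technician, minutes_per_sample: 51.43, equipment_annual_cost: 3216.0}
      - {label: "Capture", role: technician, minutes_per_sample: 19.29}
      - {label: "Sequencing run incl. checks", role: technician, minutes_per_run: 960.0, material_cost_per_run: run_material, equipment_annual_cost: sequencer_equipment}
      - {label: "Data synchronisation and run QC", role: bioinformatician, minutes_per_sample: 4.29, minutes_per_run: 90.0}
      - {label: "Batch analysis review and approval", role: molecular_biologist, minutes_per_run: 240.0, equipment_annual_cost: 51236.0}
      - {label: "Per-sample conclusion and approval", role: molecular_biologist, minutes_per_sample: 30.0}
      - {label: "Result entry in MD and patient database", role: secretary, minutes_per_sample: 15.0}
      - {label: "Approval of result and lab form", role: molecular_biologist, minutes_per_sample: 5.0}
      - {label: "Approval of result and lab form (pathology)", role: pathologist, minutes_per_sample: 10.0}
      - {label: "Approval of result and lab form (admin)", role: secretary, minutes_per_sample: 10.0}
      - {label: "Tumour sequencing board discussion", role: board_member, minutes_per_sample: 3.0}
      - {label: "Shared small equipment", role: technician, equipment_annual_cost: 2260.0}
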