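# National BIA model: Dutch stage-IV NSCLC and melanoma molecular
# diagnostics across the old (2012), current (2015) and future (2020)
# practice snapshots.
#
# Unit costs: the single-gene Sanger and fragment-analysis entries are the
# model's working values (294.5 / 294.0 EUR), recovered from the published
# population totals; the public cost overview rounds both to 295.  The
# printed-rounding variant ships alongside (netherlands_bia_printed.yaml).
#
# NSCLC current/peripheral uses two single-gene tests (EGFR + ALK, 590 EUR),
# the running-text convention; the table-cell variant with the combined pair
# priced at 559 EUR is in netherlands_bia_table2.yaml.

catalog:
  sanger: 294.5              # single-gene Sanger sequencing
  sequence_analysis: 295.0   # single-gene PCR/sequence analysis (EGFR, ALK, BRAF)
  fragment_analysis: 294.0   # single-gene fragment analysis (HER2/EGFR)
  hrm: 265.0                 # high-resolution melting (BRAF)
  fish: 309.0                # fluorescence in situ hybridisation (ALK/ROS/RET/MET)
  multigene_panel: 500.0     # multigene panel < 10 genes
  tgp_small: 606.0           # small targeted gene panel (ABC result, base plan)
  tgp_medium: 1137.0         # medium targeted gene panel (ABC result, base plan)
  wgs: 1100.0                # whole-genome sequencing, projected per-patient price

scenarios:
  # --- NSCLC -------------------------------------------------------------
  - timeframe: old_2012
    indication: nsclc
    stratum: peripheral
    patient_share: 0.7
    bundle:
      - {test: sequence_analysis, fraction: 1.0}   # EGFR
  - timeframe: old_2012
    indication: nsclc
    stratum: specialised
    patient_share: 0.3
    bundle:
      - {test: multigene_panel, fraction: 1.0}
      - {test: fragment_analysis, fraction: 1.0}   # HER2/EGFR
      - {test: fish, fraction: 1.0}                # ALK, ROS, RET or MET
  - timeframe: current_2015
    indication: nsclc
    stratum: peripheral
    patient_share: 0.7
    bundle:
      - {test: sequence_analysis, fraction: 1.0}   # EGFR
      - {test: sequence_analysis, fraction: 1.0}   # ALK
  - timeframe: current_2015
    indication: nsclc
    stratum: specialised
    patient_share: 0.3
    bundle:
      - {test: tgp_small, fraction: 1.0}
      - {test: fragment_analysis, fraction: 1.0}   # HER2/EGFR
      - {test: sanger, fraction: 1.0}              # EGFR
      - {test: fish, fraction: 1.0}                # ALK, ROS, RET or MET
  - timeframe: future_2020
    indication: nsclc
    stratum: peripheral
    patient_share: 0.7
    bundle:
      - {test: tgp_small, fraction: 1.0}
  - timeframe: future_2020
    indication: nsclc
    stratum: specialised
    patient_share: 0.3
    bundle:
      - {test: wgs, fraction: 1.0}
  # --- Melanoma ----------------------------------------------------------
  - timeframe: old_2012
    indication: melanoma
    stratum: peripheral
    patient_share: 0.3
    bundle:
      - {test: sequence_analysis, fraction: 1.0}   # BRAF
  - timeframe: old_2012
    indication: melanoma
    stratum: specialised
    patient_share: 0.7
    bundle:
      - {test: hrm, fraction: 1.0}                 # BRAF
      - {test: sanger, fraction: 1.0}              # NRAS or KIT
  - timeframe: current_2015
    indication: melanoma
    stratum: peripheral
    patient_share: 0.3
    bundle:
      - {test: sequence_analysis, fraction: 1.0}   # BRAF
  - timeframe: current_2015
    indication: melanoma
    stratum: specialised
    patient_share: 0.7
    bundle:
      - {test: tgp_small, fraction: 1.0}
      - {test: sanger, fraction: 0.5}              # KIT, in half of the patients
  - timeframe: future_2020
    indication: melanoma
    stratum: peripheral
    patient_share: 0.3
    bundle:
      - {test: tgp_small, fraction: 1.0}
  - timeframe: future_2020
    indication: melanoma
    stratum: specialised
    patient_share: 0.7
    bundle:
      - {test: wgs, fraction: 1.0}

populations:
  - {timeframe: old_2012, indication: nsclc, patients_per_year: 4045}
  - {timeframe: current_2015, indication: nsclc, patients_per_year: 4045}
  - {timeframe: future_2020, indication: nsclc, patients_per_year: 4474}
  - {timeframe: old_2012, indication: melanoma, patients_per_year: 800}
  - {timeframe: current_2015, indication: melanoma, patients_per_year: 800}
  - {timeframe: future_2020, indication: melanoma, patients_per_year: 887}
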