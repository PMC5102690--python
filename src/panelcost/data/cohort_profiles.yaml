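# Synthetic cohort profiles matching the published institutional
# before/after aggregates: cohort sizes, mean (min-max) tests per patient,
# mean mutations, and treatment/mutation category proportions.
#
# The patient-level records behind those aggregates are not published; the
# test mixes below are modelling choices tuned so the implied mean cost per
# patient is close to the published period means.  Category proportions are
# the published count/n ratios.

profiles:
  nsclc_before:
    indication: nsclc
    period: before
    n_patients: 47
    tests_mean: 2.04
    tests_min: 1
    tests_max: 4
    mutation_mean: 0.71
    mutation_min: 0
    mutation_max: 3
    test_mix:
      multigene_panel: 0.75
      sequence_analysis: 0.10
      fish: 0.06
      sanger: 0.04
      fragment_analysis: 0.03
      hrm: 0.02
    category_probs:
      ema_target_available: 0.1489      # 7/47
      trial_target_available: 0.2340    # 11/47
      started_ema_tt: 0.0426            # 2/47
      included_tt_trial: 0.0851         # 4/47
      tt_option_no_start: 0.0213        # 1/47
      trial_without_tt: 0.1064          # 5/47
      monoclonal_antibody: 0.0
      monoclonal_antibody_trial: 0.0
      radiotherapy_chemotherapy: 0.3191 # 15/47
      operation: 0.0
      no_treatment_option: 0.2979       # 14/47
      treated_elsewhere: 0.1277         # 6/47
  nsclc_after:
    indication: nsclc
    period: after
    n_patients: 53
    tests_mean: 3.0
    tests_min: 1
    tests_max: 8
    mutation_mean: 1.06
    mutation_min: 0
    mutation_max: 4
    test_mix:
      tgp_small: 0.17
      sequence_analysis: 0.18
      sanger: 0.14
      fragment_analysis: 0.15
      hrm: 0.09
      fish: 0.17
      multigene_panel: 0.09
      tgp_medium: 0.01
    category_probs:
      ema_target_available: 0.1132      # 6/53
      trial_target_available: 0.2075    # 11/53
      started_ema_tt: 0.0566            # 3/53
      included_tt_trial: 0.0377         # 2/53
      tt_option_no_start: 0.0943        # 5/53
      trial_without_tt: 0.0377          # 2/53
      monoclonal_antibody: 0.0
      monoclonal_antibody_trial: 0.0
      radiotherapy_chemotherapy: 0.3774 # 20/53
      operation: 0.0
      no_treatment_option: 0.2453       # 13/53
      treated_elsewhere: 0.1509         # 8/53
  melanoma_before:
    indication: melanoma
    period: before
    n_patients: 36
    tests_mean: 2.42
    tests_min: 1
    tests_max: 5
    mutation_mean: 0.75
    mutation_min: 0
    mutation_max: 1
    test_mix:
      sequence_analysis: 0.35
      sanger: 0.18
      fragment_analysis: 0.15
      hrm: 0.12
      fish: 0.20
    category_probs:
      ema_target_available: 0.3889      # 14/36
      trial_target_available: 0.0
      started_ema_tt: 0.1667            # 6/36
      included_tt_trial: 0.0
      tt_option_no_start: 0.1389        # 5/36
      trial_without_tt: 0.0278          # 1/36
      monoclonal_antibody: 0.1389       # 5/36
      monoclonal_antibody_trial: 0.0556 # 2/36
      radiotherapy_chemotherapy: 0.2222 # 8/36
      operation: 0.0556                 # 2/36
      no_treatment_option: 0.0556       # 2/36
      treated_elsewhere: 0.1389         # 5/36
  melanoma_after:
    indication: melanoma
    period: after
    n_patients: 36
    tests_mean: 1.67
    tests_min: 1
    tests_max: 3
    mutation_mean: 1.11
    mutation_min: 0
    mutation_max: 3
    test_mix:
      tgp_small: 0.42
      sequence_analysis: 0.25
      sanger: 0.14
      hrm: 0.12
      multigene_panel: 0.07
    category_probs:
      ema_target_available: 0.5833      # 21/36
      trial_target_available: 0.0
      started_ema_tt: 0.0833            # 3/36
      included_tt_trial: 0.0556         # 2/36
      tt_option_no_start: 0.0278        # 1/36
      trial_without_tt: 0.0
      monoclonal_antibody: 0.2222       # 8/36
      monoclonal_antibody_trial: 0.0833 # 3/36
      radiotherapy_chemotherapy: 0.1944 # 7/36
      operation: 0.0833                 # 3/36
      no_treatment_option: 0.0833       # 3/36
      treated_elsewhere: 0.1667         # 6/36
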