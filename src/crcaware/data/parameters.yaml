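adverse_events:
  bleed_cost: 278.0
  bleed_hospitalisation_prob: 0.003
  death_given_perforation: 0.052
  perforation_cost: 5089.0
  perforation_prob_no_polypectomy: 0.0
  perforation_prob_polypectomy: 0.003
behaviour:
  col_followup_compliance: 0.79
  col_surveillance_compliance: 0.83
  ever_participation: 0.63
  mean_tests_completed: 1.08
  per_round_uptake: 0.54
  repeat_test_rate: 0.07
campaign:
  campaign_cost_per_person: 0.14
  duration_months: 1
  gp_attendances_per_person: 0.0014
  gp_visit_cost: 36.0
  proportion_additional: 0.5
  secondary_appointments_per_person: 1.52606e-05
  secondary_visit_cost: 200.0
  stage_multipliers:
    A: 0.1
    B: 0.1
    C: 0.1
    D: 0.1
economics:
  cost_colonoscopy: 563.0
  cost_gfobt_noncomplier: 2.03
  cost_gfobt_normal: 3.36
  cost_gfobt_positive: 11.94
  cost_pathology: 26.0
  discount_rate: 0.035
  treatment_age_mapping: max_at_youngest
  treatment_cost_ranges:
    A:
    - 1320.0
    - 8375.0
    B:
    - 1479.0
    - 8362.0
    C:
    - 1493.0
    - 13862.0
    D:
    - 772.0
    - 11198.0
  utility_cancer_free: 0.8
  utility_crc: 0.7
  wtp_threshold: 20000.0
natural_history:
  adenoma_onset:
    anchors:
    - - 30.0
      - 0.021
    - - 50.0
      - 0.02
    - - 70.0
      - 0.045
    - - 100.0
      - 0.011
  adenomas_per_carrier: 1.9
  advanced_hr_fraction: 0.75
  hr_to_crcA:
    anchors:
    - - 30.0
      - 0.029
    - - 50.0
      - 0.025
    - - 70.0
      - 0.054
    - - 100.0
      - 0.115
  lr_to_hr:
    anchors:
    - - 30.0
      - 0.009
    - - 50.0
      - 0.008
    - - 70.0
      - 0.008
    - - 100.0
      - 0.004
  normal_to_crcA: 4.0e-05
  presentation:
    A: 0.04
    B: 0.18
    C: 0.37
    D: 0.74
  proximal_fraction: 0.38
  stage_progression:
    A: 0.51
    B: 0.69
    C: 0.71
tests:
  col_sens:
    CRC: 0.98
    HR: 0.98
    LR: 0.77
  col_spec: 1.0
  gfobt_sens:
    CRC: 0.24
    HR: 0.12
    LR: 0.01
  gfobt_spec:
    anchors:
    - - 50.0
      - 0.99
    - - 70.0
      - 0.97
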