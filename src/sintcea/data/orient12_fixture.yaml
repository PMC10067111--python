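config:
  cycle_length_days: 21.0
  horizon_years: 20.0
  discount_rate: 0.05
  wtp: 35663.0
  convention: anchored
  survival_time_unit: cycle
  half_cycle_correction: false
  death_cycle_fraction: 0.5
patient:
  bsa: 1.72
  crcl: 70.0
costs:
  drug_prices:
    sintilimab: 334.82
    gemcitabine: 70.53
    cisplatin: 8.8
    carboplatin: 1.3
    docetaxel: 39.53
    anlotinib: 665.97
  routine_followup: 55.6
  bsc: 337.5
  palliative: 2627.8
  ae_first_line:
    sintilimab_gp: 2564.35
    gp: 2412.56
utilities:
  u_pfs: 0.856
  u_fdp: 0.768
  u_sdp: 0.703
  u_endstage: 0.703
  ae_disutility:
    sintilimab_gp: 0.1
    gp: 0.097
strategies:
  first_line_sintilimab:
    name: first-line sintilimab
    ae_key: sintilimab_gp
    line1:
      name: sintilimab + gemcitabine/platinum
      os:
        family: loglogistic
        params:
        - 0.001495
        - 1.977611
      pfs:
        family: loglogistic
        params:
        - 0.009008
        - 2.158257
      disc_prob: 0.003701
      regimen:
      - drug: sintilimab
        units: 1.0
        scaling: flat
        max_cycles: null
      - drug: gemcitabine
        units: 1.0
        scaling: per_bsa
        max_cycles: 6
      - drug: cisplatin
        units: 1.0
        scaling: per_bsa
        max_cycles: 6
    line2:
      name: docetaxel
      os:
        family: loglogistic
        params:
        - 0.0224
        - 1.5206
      pfs:
        family: loglogistic
        params:
        - 0.09011
        - 1.84392
      disc_prob: 0.004685
      regimen:
      - drug: docetaxel
        units: 1.0
        scaling: per_bsa
        max_cycles: null
    line3:
      name: anlotinib
      os:
        family: weibull
        params:
        - 0.04383
        - 1.04113
      pfs:
        family: weibull
        params:
        - 0.06208
        - 1.22868
      disc_prob: 0.007211
      regimen:
      - drug: anlotinib
        units: 1.0
        scaling: flat
        max_cycles: null
  second_line_sintilimab:
    name: second-line sintilimab
    ae_key: gp
    line1:
      name: gemcitabine/platinum
      os:
        family: loglogistic
        params:
        - 0.01205
        - 1.3888
      pfs:
        family: loglogistic
        params:
        - 0.000821
        - 3.689725
      disc_prob: 0.003472
      regimen:
      - drug: gemcitabine
        units: 1.0
        scaling: per_bsa
        max_cycles: 6
      - drug: cisplatin
        units: 1.0
        scaling: per_bsa
        max_cycles: 6
    line2:
      name: sintilimab
      os:
        family: loglogistic
        params:
        - 0.009967
        - 1.617333
      pfs:
        family: loglogistic
        params:
        - 0.1094
        - 1.1974
      disc_prob: 0.007897
      regimen:
      - drug: sintilimab
        units: 1.0
        scaling: flat
        max_cycles: null
    line3:
      name: anlotinib
      os:
        family: weibull
        params:
        - 0.04383
        - 1.04113
      pfs:
        family: weibull
        params:
        - 0.06208
        - 1.22868
      disc_prob: 0.007211
      regimen:
      - drug: anlotinib
        units: 1.0
        scaling: flat
        max_cycles: null
parameters:
- name: disc_first_line_sintilimab_gp
  baseline: 0.003701
  low: 0.00185
  high: 0.005551
  psa_family: beta
  paths:
  - strategies.first_line_sintilimab.line1.disc_prob
- name: disc_first_line_gp
  baseline: 0.003472
  low: 0.001736
  high: 0.005207
  psa_family: beta
  paths:
  - strategies.second_line_sintilimab.line1.disc_prob
- name: disc_second_line_sintilimab
  baseline: 0.007897
  low: 0.003948
  high: 0.011845
  psa_family: beta
  paths:
  - strategies.second_line_sintilimab.line2.disc_prob
- name: disc_second_line_docetaxel
  baseline: 0.004685
  low: 0.002343
  high: 0.007028
  psa_family: beta
  paths:
  - strategies.first_line_sintilimab.line2.disc_prob
- name: disc_third_line_anlotinib
  baseline: 0.007211
  low: 0.003606
  high: 0.010817
  psa_family: beta
  paths:
  - strategies.first_line_sintilimab.line3.disc_prob
  - strategies.second_line_sintilimab.line3.disc_prob
- name: cost_sintilimab_200mg
  baseline: 334.82
  low: 167.41
  high: 502.23
  psa_family: gamma
  paths:
  - costs.drug_prices.sintilimab
- name: cost_gemcitabine_per_g_m2
  baseline: 70.53
  low: 35.26
  high: 105.79
  psa_family: gamma
  paths:
  - costs.drug_prices.gemcitabine
- name: cost_cisplatin_per_75mg_m2
  baseline: 8.8
  low: 4.4
  high: 13.2
  psa_family: gamma
  paths:
  - costs.drug_prices.cisplatin
- name: cost_carboplatin_per_auc5
  baseline: 1.3
  low: 0.65
  high: 1.95
  psa_family: gamma
  paths:
  - costs.drug_prices.carboplatin
- name: cost_docetaxel_per_75mg_m2
  baseline: 39.53
  low: 19.76
  high: 59.29
  psa_family: gamma
  paths:
  - costs.drug_prices.docetaxel
- name: cost_anlotinib_per_168mg
  baseline: 665.97
  low: 332.99
  high: 998.96
  psa_family: gamma
  paths:
  - costs.drug_prices.anlotinib
- name: cost_routine_followup_per_cycle
  baseline: 55.6
  low: 27.8
  high: 83.4
  psa_family: gamma
  paths:
  - costs.routine_followup
- name: cost_bsc_per_cycle
  baseline: 337.5
  low: 168.75
  high: 506.25
  psa_family: gamma
  paths:
  - costs.bsc
- name: cost_palliative_per_cycle
  baseline: 2627.8
  low: 1313.9
  high: 3941.7
  psa_family: gamma
  paths:
  - costs.palliative
- name: cost_ae_first_line_sintilimab_gp
  baseline: 2564.35
  low: 1282.18
  high: 3846.53
  psa_family: gamma
  paths:
  - costs.ae_first_line.sintilimab_gp
- name: cost_ae_first_line_gp
  baseline: 2412.56
  low: 1206.28
  high: 3618.84
  psa_family: gamma
  paths:
  - costs.ae_first_line.gp
- name: utility_pfs
  baseline: 0.856
  low: 0.718
  high: 0.994
  psa_family: beta
  paths:
  - utilities.u_pfs
- name: utility_fdp
  baseline: 0.768
  low: 0.595
  high: 0.941
  psa_family: beta
  paths:
  - utilities.u_fdp
- name: utility_sdp
  baseline: 0.703
  low: 0.545
  high: 0.861
  psa_family: beta
  paths:
  - utilities.u_sdp
- name: utility_end_stage
  baseline: 0.703
  low: 0.545
  high: 0.861
  psa_family: beta
  paths:
  - utilities.u_endstage
- name: disutility_ae_sintilimab_gp
  baseline: 0.1
  low: 0.05
  high: 0.15
  psa_family: beta
  paths:
  - utilities.ae_disutility.sintilimab_gp
- name: disutility_ae_gp
  baseline: 0.097
  low: 0.049
  high: 0.146
  psa_family: beta
  paths:
  - utilities.ae_disutility.gp
- name: discount_rate
  baseline: 0.05
  low: 0.0
  high: 0.08
  psa_family: fixed
  paths:
  - config.discount_rate
- name: body_surface_area
  baseline: 1.72
  low: 0.86
  high: 2.58
  psa_family: normal
  paths:
  - patient.bsa
- name: creatinine_clearance
  baseline: 70.0
  low: 35.0
  high: 105.0
  psa_family: normal
  paths:
  - patient.crcl
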