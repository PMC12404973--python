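# Toripalimab + chemotherapy vs chemotherapy alone, ES-SCLC, overall
# population, Chinese healthcare-system perspective.
#
# Every number below transcribes a cell of the published model-parameter
# tables (China: main parameter table and AE parameter table); values printed
# as percentages are written as fractions, currency is USD (the source
# converted CNY at 7.0467 CNY/USD).  Leaves written as
# {value, range, dist} feed the sensitivity-analysis registry; plain numbers
# are held fixed (the source publishes no ranges for them).

id: china_overall
description: >
  Overall trial population, China perspective. Survival parameters are the
  published log-logistic fits to the digitized OS/PFS curves.

labels:
  treat: toripalimab_chemo
  comp: chemo

settings:
  cycle_length_days: 21
  horizon_years: 10
  # Printed "Discount rate (China) 5%", range 4.00%-6.00%, Beta.
  discount_rate: {value: 0.05, range: [0.04, 0.06], dist: beta}
  # WTP = 3x 2023 per-capita GDP of China, USD/QALY.
  wtp: 38042.49
  # The published fits are only internally consistent with the base-case
  # results when read on the model's own cycle grid (one curve-time unit per
  # 21-day cycle); see docs/methods.md, "Time-grid calibration".
  curve_time_per_cycle: 1.0

survival:
  # Transcribed verbatim.  CAUTION, two known transcription artifacts in the
  # source table's overall-population PFS rows:
  #   * treat PFS (shape 1.839, scale 22.624) duplicates the ITH-L subgroup
  #     treat OS row and implies a median PFS longer than median OS;
  #   * comp PFS scale 15.128 coincides with the comp OS scale 15.127.
  # Both rows are kept as printed; the cohort model clamps PFS occupancy at
  # OS.  Consequences for reproducibility are analysed in docs/methods.md.
  treat:
    os: {family: loglogistic, params: {shape: 2.558, scale: 17.166}}
    pfs: {family: loglogistic, params: {shape: 1.839, scale: 22.624}}
  comp:
    os: {family: loglogistic, params: {shape: 2.734, scale: 15.127}}
    pfs: {family: loglogistic, params: {shape: 2.603, scale: 15.128}}

costs:
  drug: # $ per 21-day cycle
    toripalimab: {value: 346.07, range: [276.86, 415.28], dist: gamma}
    carboplatin: {value: 51.26, range: [41.01, 61.51], dist: gamma}
    cisplatin: {value: 35.03, range: [28.02, 42.04], dist: gamma}
    etoposide: {value: 6.63, range: [5.30, 7.96], dist: gamma} # per dose day; given days 1-3
    topotecan: {value: 246.69, range: [197.35, 296.03], dist: gamma}
    anlotinib: {value: 563.24, range: [450.59, 675.89], dist: gamma}
  administration:
    mode: per_infusion
    prophylaxis_per_infusion: {value: 93.93, range: [75.14, 112.72], dist: gamma}
    infusion_fee: {value: 1.86, range: [1.49, 2.23], dist: gamma}
    prophylaxis_per_cycle: {value: 39.14, range: [31.31, 46.97], dist: gamma}
  laboratory_per_cycle: {value: 92.99, range: [74.39, 111.59], dist: gamma}
  imaging_per_scan: {value: 241.67, range: [193.34, 290.00], dist: gamma}
  best_supportive_care_per_cycle: {value: 345.60, range: [276.48, 414.72], dist: gamma}
  end_of_life: {value: 1460.30, range: [1168.24, 1752.36], dist: gamma}
  adverse_events: # management cost per grade >=3 event
    anaemia: {value: 138.75, range: [112.32, 166.50], dist: gamma}
    decreased_platelet_count: {value: 1505.92, range: [1219.06, 1807.10], dist: gamma}
    decreased_neutrophil_count: {value: 115.01, range: [80.92, 138.01], dist: gamma}
    hyponatraemia: {value: 3223.00, range: [2578.40, 3867.60], dist: gamma}
    hypokalaemia: {value: 3000.00, range: [2400.00, 3600.00], dist: gamma}
    pneumonia: {value: 2105.00, range: [1684.00, 2526.00], dist: gamma}

utilities:
  pfs: {value: 0.69, range: [0.55, 0.83], dist: beta}
  pd: {value: 0.60, range: [0.48, 0.72], dist: beta}

disutilities: # one-time decrement during the first model cycle
  anaemia: {value: 0.07, range: [0.06, 0.09], dist: beta}
  decreased_platelet_count: {value: 0.05, range: [0.04, 0.06], dist: beta}
  decreased_neutrophil_count: {value: 0.20, range: [0.16, 0.24], dist: beta}
  hyponatraemia: {value: 0.04, range: [0.03, 0.05], dist: beta}
  hypokalaemia: {value: 0.04, range: [0.03, 0.05], dist: beta}
  pneumonia: {value: 0.09, range: [0.07, 0.11], dist: beta}

adverse_event_incidence: # grade 3-4 events with incidence > 5%
  treat:
    anaemia: {value: 0.306, range: [0.2448, 0.3672], dist: beta}
    decreased_platelet_count: {value: 0.248, range: [0.1984, 0.2976], dist: beta}
    decreased_neutrophil_count: {value: 0.743, range: [0.5944, 0.8916], dist: beta}
    hyponatraemia: {value: 0.063, range: [0.0504, 0.0756], dist: beta}
    hypokalaemia: {value: 0.059, range: [0.0472, 0.0708], dist: beta}
    pneumonia: {value: 0.068, range: [0.0544, 0.0816], dist: beta}
  comp:
    anaemia: {value: 0.347, range: [0.2776, 0.4164], dist: beta}
    decreased_platelet_count: {value: 0.343, range: [0.2744, 0.4116], dist: beta}
    decreased_neutrophil_count: {value: 0.750, range: [0.6000, 0.9000], dist: beta}
    hyponatraemia: {value: 0.065, range: [0.0520, 0.0780], dist: beta}
    hypokalaemia: {value: 0.065, range: [0.0520, 0.0780], dist: beta}
    pneumonia: {value: 0.032, range: [0.0256, 0.0384], dist: beta}

subsequent_treatment:
  # Shares describe overlapping therapy lines (they sum to 95.5% / 128.3%);
  # the model renormalizes them to 1 within the treated fraction.
  treat:
    proportion: {value: 0.552, range: [0.4416, 0.6624], dist: beta}
    shares:
      cytotoxic: {value: 0.493, range: [0.3944, 0.5916], dist: beta}
      tki: {value: 0.323, range: [0.2584, 0.3876], dist: beta}
      pd1: {value: 0.139, range: [0.1112, 0.1668], dist: beta}
  comp:
    proportion: {value: 0.694, range: [0.5552, 0.8328], dist: beta}
    shares:
      cytotoxic: {value: 0.594, range: [0.4752, 0.7128], dist: beta}
      tki: {value: 0.438, range: [0.3504, 0.5256], dist: beta}
      pd1: {value: 0.251, range: [0.2008, 0.3012], dist: beta}

schedule:
  induction_cycles: 4
  induction_infusion_days: 3 # etoposide days 1-3; carboplatin + antibody day 1
  maintenance_infusion_days: 1
  imaging_interval_early: 2 # scans every 6 weeks ...
  imaging_switch_cycle: 18 # ... through week 54 ...
  imaging_interval_late: 4 # ... then every 12 weeks

maintenance_drug:
  treat: toripalimab # Q3W until progression; no duration cap
  comp: null # placebo maintenance carries no drug or administration cost
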