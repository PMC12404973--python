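# Toripalimab + chemotherapy vs chemotherapy alone, ES-SCLC, overall
# population, United States payer perspective.
#
# Survival parameters are identical to the China scenarios (one trial, one
# set of digitized curves); costs come from the published US parameter
# table, utilities/disutilities/AE incidences and subsequent-treatment
# proportions are common to both perspectives.  Discounting is 3% annually.

id: us_overall
extends: china_overall
description: >
  Overall trial population, US payer perspective. US cost table, 3% annual
  discounting, $150,000/QALY threshold.

settings:
  # Printed baseline 3%; the printed range "4.00%-6.00%" is inconsistent
  # with its own baseline (it duplicates the China row), so the registry
  # range is widened to 0-6% around the 3% base.
  discount_rate: {value: 0.03, range: [0.00, 0.06], dist: beta}
  wtp: 150000.00

costs:
  drug: # $ per 21-day cycle
    toripalimab: {value: 8892.03, range: [7113.62, 10670.44], dist: gamma}
    carboplatin: {value: 55.83, range: [44.66, 67.00], dist: gamma}
    cisplatin: {value: 45.79, range: [36.63, 54.95], dist: gamma}
    etoposide: {value: 62.76, range: [50.21, 75.31], dist: gamma}
    topotecan: {value: 2720.26, range: [2176.21, 3264.31], dist: gamma}
    # The US table prints no anlotinib (TKI) price.  The China per-cycle
    # price is used as an explicit default so the gap stays in the data,
    # not the code; override here if a US acquisition cost is available.
    anlotinib: {value: 563.24, range: [450.59, 675.89], dist: gamma}
  administration:
    mode: per_hour
    first_hour: {value: 142.55, range: [114.04, 171.06], dist: gamma}
    additional_hour: {value: 30.68, range: [24.54, 36.82], dist: gamma}
  laboratory_per_cycle: {value: 111.65, range: [89.32, 133.98], dist: gamma}
  imaging_per_scan: {value: 438.21, range: [350.568, 525.85], dist: gamma}
  best_supportive_care_per_cycle: {value: 1447.79, range: [1158.23, 1737.35], dist: gamma}
  end_of_life: {value: 21603.00, range: [17282.40, 25923.60], dist: gamma}
  adverse_events:
    anaemia: {value: 7941.00, range: [6352.80, 9529.20], dist: gamma}
    decreased_platelet_count: {value: 13105.00, range: [10484.00, 15726.00], dist: gamma}
    decreased_neutrophil_count: {value: 13105.00, range: [10484.00, 15726.00], dist: gamma}
    hyponatraemia: {value: 4685.00, range: [3748.00, 5622.00], dist: gamma}
    hypokalaemia: {value: 4685.00, range: [3748.00, 5622.00], dist: gamma}
    pneumonia: {value: 10756.00, range: [8604.80, 12907.20], dist: gamma}
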