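# HLA-A11+/B62- subgroup, US payer perspective: subgroup survival fits with
# the US cost table (see us_overall for cost provenance notes).

id: us_a11_b62
extends: us_overall
description: >
  HLA-A11+/B62- subgroup, US payer perspective. Subgroup survival fits; US
  costs, 3% discounting, $150,000/QALY threshold.

survival:
  treat:
    os: {family: lognormal, params: {meanlog: 3.062, sdlog: 0.507}}
    pfs: {family: lognormal, params: {meanlog: 2.154, sdlog: 0.643}}
  comp:
    os: {family: lognormal, params: {meanlog: 2.733, sdlog: 0.638}}
    pfs: {family: loglogistic, params: {shape: 3.078, scale: 5.934}}
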