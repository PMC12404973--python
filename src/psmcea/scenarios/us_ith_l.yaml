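# ITH-L subgroup, US payer perspective: subgroup survival fits with the US
# cost table (see us_overall for cost provenance notes).

id: us_ith_l
extends: us_overall
description: >
  ITH-L subgroup, US payer perspective. Subgroup survival fits; US costs,
  3% discounting, $150,000/QALY threshold.

survival:
  treat:
    os: {family: loglogistic, params: {shape: 1.839, scale: 22.624}}
    pfs: {family: lognormal, params: {meanlog: 2.169, sdlog: 0.876}}
  comp:
    os: {family: generalized_gamma, params: {mu: 2.4562, sigma: 0.6261, Q: -0.9901}}
    pfs: {family: loglogistic, params: {shape: 3.589, scale: 6.302}}
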