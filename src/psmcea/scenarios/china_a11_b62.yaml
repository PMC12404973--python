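# HLA-A11+/B62- haplotype subgroup, China perspective.  Only the survival
# parameter sets differ from china_overall (no subgroup-specific cost,
# utility or AE data were published).

id: china_a11_b62
extends: china_overall
description: >
  HLA-A11+/B62- subgroup, China perspective. Subgroup survival fits; all
  cost, utility and AE inputs inherited from the overall population.

survival:
  treat:
    os: {family: lognormal, params: {meanlog: 3.062, sdlog: 0.507}}
    pfs: {family: lognormal, params: {meanlog: 2.154, sdlog: 0.643}}
  comp:
    os: {family: lognormal, params: {meanlog: 2.733, sdlog: 0.638}}
    pfs: {family: loglogistic, params: {shape: 3.078, scale: 5.934}}
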