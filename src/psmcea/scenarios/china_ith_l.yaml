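# Low intratumor heterogeneity (ITH-L, MATH score < 29) subgroup, China
# perspective.  Only the survival parameter sets differ from china_overall:
# the source trial published no subgroup-specific follow-up treatment, drug
# use or AE incidence, so those are the overall-population values.

id: china_ith_l
extends: china_overall
description: >
  ITH-L subgroup, China perspective. Subgroup survival fits; all cost,
  utility and AE inputs inherited from the overall population.

survival:
  treat:
    os: {family: loglogistic, params: {shape: 1.839, scale: 22.624}}
    pfs: {family: lognormal, params: {meanlog: 2.169, sdlog: 0.876}}
  comp:
    os: {family: generalized_gamma, params: {mu: 2.4562, sigma: 0.6261, Q: -0.9901}}
    pfs: {family: loglogistic, params: {shape: 3.589, scale: 6.302}}
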