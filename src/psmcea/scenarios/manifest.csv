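scenario_id,key,value
china_a11_b62,survival.comp.os.meanlog,2.733
china_a11_b62,survival.comp.os.sdlog,0.638
china_a11_b62,survival.comp.pfs.scale,5.934
china_a11_b62,survival.comp.pfs.shape,3.078
china_a11_b62,survival.treat.os.meanlog,3.062
china_a11_b62,survival.treat.os.sdlog,0.507
china_a11_b62,survival.treat.pfs.meanlog,2.154
china_a11_b62,survival.treat.pfs.sdlog,0.643
china_ith_l,survival.comp.os.Q,-0.9901
china_ith_l,survival.comp.os.mu,2.4562
china_ith_l,survival.comp.os.sigma,0.6261
china_ith_l,survival.comp.pfs.scale,6.302
china_ith_l,survival.comp.pfs.shape,3.589
china_ith_l,survival.treat.os.scale,22.624
china_ith_l,survival.treat.os.shape,1.839
china_ith_l,survival.treat.pfs.meanlog,2.169
china_ith_l,survival.treat.pfs.sdlog,0.876
china_overall,adverse_event_incidence.comp.anaemia,0.347
china_overall,adverse_event_incidence.comp.decreased_neutrophil_count,0.75
china_overall,adverse_event_incidence.comp.decreased_platelet_count,0.343
china_overall,adverse_event_incidence.comp.hypokalaemia,0.065
china_overall,adverse_event_incidence.comp.hyponatraemia,0.065
china_overall,adverse_event_incidence.comp.pneumonia,0.032
china_overall,adverse_event_incidence.treat.anaemia,0.306
china_overall,adverse_event_incidence.treat.decreased_neutrophil_count,0.743
china_overall,adverse_event_incidence.treat.decreased_platelet_count,0.248
china_overall,adverse_event_incidence.treat.hypokalaemia,0.059
china_overall,adverse_event_incidence.treat.hyponatraemia,0.063
china_overall,adverse_event_incidence.treat.pneumonia,0.068
china_overall,costs.administration.infusion_fee,1.86
china_overall,costs.administration.prophylaxis_per_cycle,39.14
china_overall,costs.administration.prophylaxis_per_infusion,93.93
china_overall,costs.adverse_events.anaemia,138.75
china_overall,costs.adverse_events.decreased_neutrophil_count,115.01
china_overall,costs.adverse_events.decreased_platelet_count,1505.92
china_overall,costs.adverse_events.hypokalaemia,3000.0
china_overall,costs.adverse_events.hyponatraemia,3223.0
china_overall,costs.adverse_events.pneumonia,2105.0
china_overall,costs.best_supportive_care_per_cycle,345.6
china_overall,costs.drug.anlotinib,563.24
china_overall,costs.drug.carboplatin,51.26
china_overall,costs.drug.cisplatin,35.03
china_overall,costs.drug.etoposide,6.63
china_overall,costs.drug.topotecan,246.69
china_overall,costs.drug.toripalimab,346.07
china_overall,costs.end_of_life,1460.3
china_overall,costs.imaging_per_scan,241.67
china_overall,costs.laboratory_per_cycle,92.99
china_overall,disutilities.anaemia,0.07
china_overall,disutilities.decreased_neutrophil_count,0.2
china_overall,disutilities.decreased_platelet_count,0.05
china_overall,disutilities.hypokalaemia,0.04
china_overall,disutilities.hyponatraemia,0.04
china_overall,disutilities.pneumonia,0.09
china_overall,settings.discount_rate,0.05
china_overall,settings.wtp,38042.49
china_overall,subsequent_treatment.comp.proportion,0.694
china_overall,subsequent_treatment.comp.shares.cytotoxic,0.594
china_overall,subsequent_treatment.comp.shares.pd1,0.251
china_overall,subsequent_treatment.comp.shares.tki,0.438
china_overall,subsequent_treatment.treat.proportion,0.552
china_overall,subsequent_treatment.treat.shares.cytotoxic,0.493
china_overall,subsequent_treatment.treat.shares.pd1,0.139
china_overall,subsequent_treatment.treat.shares.tki,0.323
china_overall,survival.comp.os.scale,15.127
china_overall,survival.comp.os.shape,2.734
china_overall,survival.comp.pfs.scale,15.128
china_overall,survival.comp.pfs.shape,2.603
china_overall,survival.treat.os.scale,17.166
china_overall,survival.treat.os.shape,2.558
china_overall,survival.treat.pfs.scale,22.624
china_overall,survival.treat.pfs.shape,1.839
china_overall,utilities.pd,0.6
china_overall,utilities.pfs,0.69
us_a11_b62,survival.comp.os.meanlog,2.733
us_a11_b62,survival.comp.os.sdlog,0.638
us_a11_b62,survival.comp.pfs.scale,5.934
us_a11_b62,survival.comp.pfs.shape,3.078
us_a11_b62,survival.treat.os.meanlog,3.062
us_a11_b62,survival.treat.os.sdlog,0.507
us_a11_b62,survival.treat.pfs.meanlog,2.154
us_a11_b62,survival.treat.pfs.sdlog,0.643
us_ith_l,survival.comp.os.Q,-0.9901
us_ith_l,survival.comp.os.mu,2.4562
us_ith_l,survival.comp.os.sigma,0.6261
us_ith_l,survival.comp.pfs.scale,6.302
us_ith_l,survival.comp.pfs.shape,3.589
us_ith_l,survival.treat.os.scale,22.624
us_ith_l,survival.treat.os.shape,1.839
us_ith_l,survival.treat.pfs.meanlog,2.169
us_ith_l,survival.treat.pfs.sdlog,0.876
us_overall,costs.administration.additional_hour,30.68
us_overall,costs.administration.first_hour,142.55
us_overall,costs.adverse_events.anaemia,7941.0
us_overall,costs.adverse_events.decreased_neutrophil_count,13105.0
us_overall,costs.adverse_events.decreased_platelet_count,13105.0
us_overall,costs.adverse_events.hypokalaemia,4685.0
us_overall,costs.adverse_events.hyponatraemia,4685.0
us_overall,costs.adverse_events.pneumonia,10756.0
us_overall,costs.best_supportive_care_per_cycle,1447.79
us_overall,costs.drug.anlotinib,563.24
us_overall,costs.drug.carboplatin,55.83
us_overall,costs.drug.cisplatin,45.79
us_overall,costs.drug.etoposide,62.76
us_overall,costs.drug.topotecan,2720.26
us_overall,costs.drug.toripalimab,8892.03
us_overall,costs.end_of_life,21603.0
us_overall,costs.imaging_per_scan,438.21
us_overall,costs.laboratory_per_cycle,111.65
us_overall,settings.discount_rate,0.03
us_overall,settings.wtp,150000.0
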