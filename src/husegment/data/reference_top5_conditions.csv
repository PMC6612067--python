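# Reference top-five primary-diagnosis (CCS) condition lists per high-utilizer
# group, with patients-ever-diagnosed counts, from a published large
# academic-medical-center cohort. Used for in-print arithmetic cross-checks
# (union of lists, group-percentage recomputation); not produced by this
# package's generator.
group,rank,condition,patients_ever
NonHU,1,Superficial injury; contusion,27049
NonHU,2,Other upper respiratory infections,14778
NonHU,3,Sprains and strains,14546
NonHU,4,Non-infectious gastroenteritis,12371
NonHU,5,Open wounds of extremities,11447
Cost,1,Coronary atherosclerosis and other heart disease,2946
Cost,2,Acute myocardial infarction,2877
Cost,3,Acute cerebrovascular disease,879
Cost,4,Essential hypertension,781
Cost,5,Fracture of lower limb,604
LOS,1,Mood disorders,52
LOS,2,Schizophrenia and other psychotic disorders,36
LOS,3,Residual codes; unclassified,17
LOS,4,Pneumonia,13
LOS,5,Intracranial injury,12
SOC,1,Normal pregnancy and delivery,3490
SOC,2,Cataract,1379
SOC,3,Other complications of birth,1151
SOC,4,Fracture of upper limb,1055
SOC,5,Gastritis and duodenitis,743
LOS_SOC,1,Mood disorders,23
LOS_SOC,2,Schizophrenia and other psychotic disorders,14
LOS_SOC,3,Other eye disorders,5
LOS_SOC,4,Superficial injury; contusion,5
LOS_SOC,5,Burns,4
Cost_LOS,1,Acute cerebrovascular disease,1049
Cost_LOS,2,Pneumonia,838
Cost_LOS,3,Urinary tract infections,546
Cost_LOS,4,Coronary atherosclerosis and other heart disease,493
Cost_LOS,5,Acute myocardial infarction,417
Cost_SOC,1,Cancer of breast,955
Cost_SOC,2,Coronary atherosclerosis and other heart disease,925
Cost_SOC,3,Female infertility,650
Cost_SOC,4,Fracture of upper limb,619
Cost_SOC,5,Essential hypertension,581
Cost_LOS_SOC,1,Coronary atherosclerosis and other heart disease,572
Cost_LOS_SOC,2,Acute cerebrovascular disease,440
Cost_LOS_SOC,3,Pneumonia,414
Cost_LOS_SOC,4,Essential hypertension,398
Cost_LOS_SOC,5,Septicemia (except in labour),363
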