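# 17-category Quan ICD-10 comorbidity coding algorithm, original Charlson weights.
# Trailing '*' marks a prefix entry; exact entries take precedence.
code,category,weight
I21*,myocardial_infarction,1
I22*,myocardial_infarction,1
I25.2,myocardial_infarction,1
I09.9,congestive_heart_failure,1
I11.0,congestive_heart_failure,1
I13.0,congestive_heart_failure,1
I13.2,congestive_heart_failure,1
I25.5,congestive_heart_failure,1
I42.0,congestive_heart_failure,1
I42.5,congestive_heart_failure,1
I42.6,congestive_heart_failure,1
I42.7,congestive_heart_failure,1
I42.8,congestive_heart_failure,1
I42.9,congestive_heart_failure,1
I43*,congestive_heart_failure,1
I50*,congestive_heart_failure,1
P29.0,congestive_heart_failure,1
I70*,peripheral_vascular_disease,1
I71*,peripheral_vascular_disease,1
I73.1,peripheral_vascular_disease,1
I73.8,peripheral_vascular_disease,1
I73.9,peripheral_vascular_disease,1
I77.1,peripheral_vascular_disease,1
I79.0,peripheral_vascular_disease,1
I79.2,peripheral_vascular_disease,1
K55.1,peripheral_vascular_disease,1
K55.8,peripheral_vascular_disease,1
K55.9,peripheral_vascular_disease,1
Z95.8,peripheral_vascular_disease,1
Z95.9,peripheral_vascular_disease,1
G45*,cerebrovascular_disease,1
G46*,cerebrovascular_disease,1
H34.0,cerebrovascular_disease,1
I60*,cerebrovascular_disease,1
I61*,cerebrovascular_disease,1
I62*,cerebrovascular_disease,1
I63*,cerebrovascular_disease,1
I64*,cerebrovascular_disease,1
I65*,cerebrovascular_disease,1
I66*,cerebrovascular_disease,1
I67*,cerebrovascular_disease,1
I68*,cerebrovascular_disease,1
I69*,cerebrovascular_disease,1
F00*,dementia,1
F01*,dementia,1
F02*,dementia,1
F03*,dementia,1
F05.1,dementia,1
G30*,dementia,1
G31.1,dementia,1
I27.8,chronic_pulmonary_disease,1
I27.9,chronic_pulmonary_disease,1
J40*,chronic_pulmonary_disease,1
J41*,chronic_pulmonary_disease,1
J42*,chronic_pulmonary_disease,1
J43*,chronic_pulmonary_disease,1
J44*,chronic_pulmonary_disease,1
J45*,chronic_pulmonary_disease,1
J46*,chronic_pulmonary_disease,1
J47*,chronic_pulmonary_disease,1
J60*,chronic_pulmonary_disease,1
J61*,chronic_pulmonary_disease,1
J62*,chronic_pulmonary_disease,1
J63*,chronic_pulmonary_disease,1
J64*,chronic_pulmonary_disease,1
J65*,chronic_pulmonary_disease,1
J66*,chronic_pulmonary_disease,1
J67*,chronic_pulmonary_disease,1
J68.4,chronic_pulmonary_disease,1
J70.1,chronic_pulmonary_disease,1
J70.3,chronic_pulmonary_disease,1
M05*,rheumatic_disease,1
M06*,rheumatic_disease,1
M31.5,rheumatic_disease,1
M32*,rheumatic_disease,1
M33*,rheumatic_disease,1
M34*,rheumatic_disease,1
M35.1,rheumatic_disease,1
M35.3,rheumatic_disease,1
M36.0,rheumatic_disease,1
K25*,peptic_ulcer_disease,1
K26*,peptic_ulcer_disease,1
K27*,peptic_ulcer_disease,1
K28*,peptic_ulcer_disease,1
B18*,mild_liver_disease,1
K70.0,mild_liver_disease,1
K70.1,mild_liver_disease,1
K70.2,mild_liver_disease,1
K70.3,mild_liver_disease,1
K70.9,mild_liver_disease,1
K71.3,mild_liver_disease,1
K71.4,mild_liver_disease,1
K71.5,mild_liver_disease,1
K71.7,mild_liver_disease,1
K73*,mild_liver_disease,1
K74*,mild_liver_disease,1
K76.0,mild_liver_disease,1
K76.2,mild_liver_disease,1
K76.3,mild_liver_disease,1
K76.4,mild_liver_disease,1
K76.8,mild_liver_disease,1
K76.9,mild_liver_disease,1
Z94.4,mild_liver_disease,1
E10.0,diabetes_without_complication,1
E10.1,diabetes_without_complication,1
E10.6,diabetes_without_complication,1
E10.8,diabetes_without_complication,1
E10.9,diabetes_without_complication,1
E11.0,diabetes_without_complication,1
E11.1,diabetes_without_complication,1
E11.6,diabetes_without_complication,1
E11.8,diabetes_without_complication,1
E11.9,diabetes_without_complication,1
E13.0,diabetes_without_complication,1
E13.1,diabetes_without_complication,1
E13.6,diabetes_without_complication,1
E13.8,diabetes_without_complication,1
E13.9,diabetes_without_complication,1
E14.0,diabetes_without_complication,1
E14.1,diabetes_without_complication,1
E14.6,diabetes_without_complication,1
E14.8,diabetes_without_complication,1
E14.9,diabetes_without_complication,1
E10.2,diabetes_with_complication,2
E10.3,diabetes_with_complication,2
E10.4,diabetes_with_complication,2
E10.5,diabetes_with_complication,2
E10.7,diabetes_with_complication,2
E11.2,diabetes_with_complication,2
E11.3,diabetes_with_complication,2
E11.4,diabetes_with_complication,2
E11.5,diabetes_with_complication,2
E11.7,diabetes_with_complication,2
E13.2,diabetes_with_complication,2
E13.3,diabetes_with_complication,2
E13.4,diabetes_with_complication,2
E13.5,diabetes_with_complication,2
E13.7,diabetes_with_complication,2
E14.2,diabetes_with_complication,2
E14.3,diabetes_with_complication,2
E14.4,diabetes_with_complication,2
E14.5,diabetes_with_complication,2
E14.7,diabetes_with_complication,2
G04.1,hemiplegia_paraplegia,2
G11.4,hemiplegia_paraplegia,2
G80.1,hemiplegia_paraplegia,2
G80.2,hemiplegia_paraplegia,2
G81*,hemiplegia_paraplegia,2
G82*,hemiplegia_paraplegia,2
G83.0,hemiplegia_paraplegia,2
G83.1,hemiplegia_paraplegia,2
G83.2,hemiplegia_paraplegia,2
G83.3,hemiplegia_paraplegia,2
G83.4,hemiplegia_paraplegia,2
G83.9,hemiplegia_paraplegia,2
I12.0,renal_disease,2
I13.1,renal_disease,2
N03.2,renal_disease,2
N03.3,renal_disease,2
N03.4,renal_disease,2
N03.5,renal_disease,2
N03.6,renal_disease,2
N03.7,renal_disease,2
N05.2,renal_disease,2
N05.3,renal_disease,2
N05.4,renal_disease,2
N05.5,renal_disease,2
N05.6,renal_disease,2
N05.7,renal_disease,2
N18*,renal_disease,2
N19*,renal_disease,2
N25.0,renal_disease,2
Z49.0,renal_disease,2
Z49.1,renal_disease,2
Z49.2,renal_disease,2
Z94.0,renal_disease,2
Z99.2,renal_disease,2
C0*,any_malignancy,2
C1*,any_malignancy,2
C20*,any_malignancy,2
C21*,any_malignancy,2
C22*,any_malignancy,2
C23*,any_malignancy,2
C24*,any_malignancy,2
C25*,any_malignancy,2
C26*,any_malignancy,2
C30*,any_malignancy,2
C31*,any_malignancy,2
C32*,any_malignancy,2
C33*,any_malignancy,2
C34*,any_malignancy,2
C37*,any_malignancy,2
C38*,any_malignancy,2
C39*,any_malignancy,2
C40*,any_malignancy,2
C41*,any_malignancy,2
C43*,any_malignancy,2
C45*,any_malignancy,2
C46*,any_malignancy,2
C47*,any_malignancy,2
C48*,any_malignancy,2
C49*,any_malignancy,2
C50*,any_malignancy,2
C51*,any_malignancy,2
C52*,any_malignancy,2
C53*,any_malignancy,2
C54*,any_malignancy,2
C55*,any_malignancy,2
C56*,any_malignancy,2
C57*,any_malignancy,2
C58*,any_malignancy,2
C60*,any_malignancy,2
C61*,any_malignancy,2
C62*,any_malignancy,2
C63*,any_malignancy,2
C64*,any_malignancy,2
C65*,any_malignancy,2
C66*,any_malignancy,2
C67*,any_malignancy,2
C68*,any_malignancy,2
C69*,any_malignancy,2
C70*,any_malignancy,2
C71*,any_malignancy,2
C72*,any_malignancy,2
C73*,any_malignancy,2
C74*,any_malignancy,2
C75*,any_malignancy,2
C76*,any_malignancy,2
C81*,any_malignancy,2
C82*,any_malignancy,2
C83*,any_malignancy,2
C84*,any_malignancy,2
C85*,any_malignancy,2
C88*,any_malignancy,2
C90*,any_malignancy,2
C91*,any_malignancy,2
C92*,any_malignancy,2
C93*,any_malignancy,2
C94*,any_malignancy,2
C95*,any_malignancy,2
C96*,any_malignancy,2
C97*,any_malignancy,2
I85.0,moderate_severe_liver_disease,3
I85.9,moderate_severe_liver_disease,3
I86.4,moderate_severe_liver_disease,3
I98.2,moderate_severe_liver_disease,3
K70.4,moderate_severe_liver_disease,3
K71.1,moderate_severe_liver_disease,3
K72.1,moderate_severe_liver_disease,3
K72.9,moderate_severe_liver_disease,3
K76.5,moderate_severe_liver_disease,3
K76.6,moderate_severe_liver_disease,3
K76.7,moderate_severe_liver_disease,3
C77*,metastatic_solid_tumour,6
C78*,metastatic_solid_tumour,6
C79*,metastatic_solid_tumour,6
C80*,metastatic_solid_tumour,6
B20*,aids_hiv,6
B21*,aids_hiv,6
B22*,aids_hiv,6
B24*,aids_hiv,6
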