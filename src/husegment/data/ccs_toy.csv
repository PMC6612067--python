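# Small CCS-style crosswalk covering the reporting condition groups used by
# the bundled examples and the synthetic cohort. Not the official crosswalk:
# load a full mapping file for real analyses.
code,category
S00*,Superficial injury; contusion
S30*,Superficial injury; contusion
T14.0,Superficial injury; contusion
J00*,Other upper respiratory infections
J02*,Other upper respiratory infections
J06*,Other upper respiratory infections
S13*,Sprains and strains
S43*,Sprains and strains
S93*,Sprains and strains
K52*,Non-infectious gastroenteritis
S61*,Open wounds of extremities
S81*,Open wounds of extremities
I25*,Coronary atherosclerosis and other heart disease
I20*,Coronary atherosclerosis and other heart disease
I21*,Acute myocardial infarction
I22*,Acute myocardial infarction
I60*,Acute cerebrovascular disease
I61*,Acute cerebrovascular disease
I63*,Acute cerebrovascular disease
I64*,Acute cerebrovascular disease
I10*,Essential hypertension
S72*,Fracture of lower limb
S82*,Fracture of lower limb
F30*,Mood disorders
F31*,Mood disorders
F32*,Mood disorders
F33*,Mood disorders
F34*,Mood disorders
F20*,Schizophrenia and other psychotic disorders
F22*,Schizophrenia and other psychotic disorders
F25*,Schizophrenia and other psychotic disorders
F29*,Schizophrenia and other psychotic disorders
J12*,Pneumonia
J13*,Pneumonia
J14*,Pneumonia
J15*,Pneumonia
J18*,Pneumonia
S06*,Intracranial injury
Z34*,Normal pregnancy and delivery
O80*,Normal pregnancy and delivery
H25*,Cataract
H26*,Cataract
O70*,Other complications of birth
O72*,Other complications of birth
O75*,Other complications of birth
S42*,Fracture of upper limb
S52*,Fracture of upper limb
S62*,Fracture of upper limb
K29*,Gastritis and duodenitis
H57*,Other eye disorders
H53*,Other eye disorders
T20*,Burns
T21*,Burns
T22*,Burns
T23*,Burns
T24*,Burns
T25*,Burns
N39*,Urinary tract infections
N30*,Urinary tract infections
C50*,Cancer of breast
N97*,Female infertility
A40*,Septicemia (except in labour)
A41*,Septicemia (except in labour)
I50*,Congestive heart failure; nonhypertensive
N18*,Chronic kidney disease
E11*,Diabetes mellitus without complication
F03*,Delirium dementia and amnestic and other cognitive disorders
C78*,Secondary malignancies
O60*,Other complications of pregnancy
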