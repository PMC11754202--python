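pt,soc
alanine aminotransferase increased,investigations
anaemia,blood and lymphatic system disorders
arthralgia,musculoskeletal and connective tissue disorders
blood creatinine increased,investigations
blood sodium decreased,investigations
cardiac failure,cardiac disorders
constipation,gastrointestinal disorders
cough,respiratory, thoracic and mediastinal disorders
decreased appetite,metabolism and nutrition disorders
dehydration,metabolism and nutrition disorders
diarrhoea,gastrointestinal disorders
dizziness,nervous system disorders
drug ineffective,general disorders and administration site conditions
dyspnoea,respiratory, thoracic and mediastinal disorders
fatigue,general disorders and administration site conditions
headache,nervous system disorders
hepatic function abnormal,hepatobiliary disorders
hypernatraemia,metabolism and nutrition disorders
hypertension,vascular disorders
hyponatraemia,metabolism and nutrition disorders
insomnia,psychiatric disorders
malaise,general disorders and administration site conditions
nausea,gastrointestinal disorders
oedema peripheral,general disorders and administration site conditions
osmotic demyelination syndrome,nervous system disorders
pollakiuria,renal and urinary disorders
polydipsia,metabolism and nutrition disorders
polyuria,renal and urinary disorders
pruritus,skin and subcutaneous tissue disorders
pyrexia,general disorders and administration site conditions
rash,skin and subcutaneous tissue disorders
renal cyst ruptured,renal and urinary disorders
renal impairment,renal and urinary disorders
thirst,general disorders and administration site conditions
vomiting,gastrointestinal disorders
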