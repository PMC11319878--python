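concept,icd10,icd9
congestive heart failure,I50.2;I50.3;I50.4,428.[2-4][0-3]
unstable angina,I20.0,411.1
acute myocardial infarction,I21,410.9[0-2]
arrhythmia,I49,429.9
torsade de pointes,I45.81,426.82
long QT syndrome,I45.81,426.82
atrial fibrillation and flutter,I48,427.3[1-2]
symptomatic bradycardia,R00.1,427.89
uncontrolled hypertension,I10,401.[09]
heart aneurysm,I25.3,414.1[09]
coronary heart disease,I25.1,414.01
cardiomyopathy,I42.9,425.[49]
vasculitis or angiitis,I77.6,447.6
pericardial effusion,I31.3,423.9
peripheral vascular disease,I73.9,443.9
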