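label,precision,recall,f1
Demographic::age,1.000,0.923,0.960
Demographic::gender,1.000,0.870,0.931
Diagnosis::histology,1.000,1.000,1.000
Diagnosis::stage,0.667,1.000,0.800
Biomarker::biomarker,1.000,0.800,0.889
Clinical status::disease status,0.737,0.684,0.709
Prior therapy::chemotherapy,0.944,0.895,0.919
Prior therapy::targeted therapy,1.000,0.786,0.880
Prior therapy::immunotherapy,0.897,0.788,0.839
Prior therapy::radiotherapy,0.682,0.682,0.682
Prior therapy::adjuvant therapy,1.000,0.571,0.727
Prior therapy::neoadjuvant therapy,1.000,0.500,0.667
Comorbidity::disease,0.842,0.762,0.800
Laboratory test::test,0.871,0.818,0.844
Vital::vital,1.000,1.000,1.000
Procedure::procedure,1.000,0.600,0.750
Other medication::medication,0.800,0.727,0.762
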