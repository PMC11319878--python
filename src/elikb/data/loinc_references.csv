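concept,loinc,unit,sample_type,popularity_rank,methodless,low_male,high_male,low_female,high_female
ALT,1742-6,U/L,serum,,true,7,56,7,56
AST,1920-8,U/L,serum,,true,10,40,10,40
Total bilirubin,1975-2,mg/dL,serum,,true,0.1,1.2,0.1,1.2
Direct bilirubin,1968-7,mg/dL,serum,,true,,0.3,,0.3
Serum creatinine,2160-0,mg/dL,serum,,true,0.6,1.2,0.5,1.1
CrCl,2164-2,mL/min,serum,,true,97,137,88,128
ANC,26499-4,cells/uL,blood,,true,1500,8000,1500,8000
Platelets,777-3,cells/uL,blood,,true,150000,450000,150000,450000
Hemoglobin,718-7,g/dL,blood,,true,12,18,12,18
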