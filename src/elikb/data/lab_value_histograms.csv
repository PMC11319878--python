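analyte,comparator,value,unit,trial_count
ALT,≤,1,xULN,6
ALT,≤,1.5,xULN,8
ALT,≤,2,xULN,10
ALT,≤,2.5,xULN,24
ALT,≤,3,xULN,12
ALT,≤,5,xULN,5
AST,≤,1,xULN,6
AST,≤,1.5,xULN,9
AST,≤,2,xULN,10
AST,≤,2.5,xULN,23
AST,≤,3,xULN,11
AST,≤,5,xULN,4
Total bilirubin,≤,1,xULN,8
Total bilirubin,≤,1.5,xULN,20
Total bilirubin,≤,2,xULN,7
Total bilirubin,≤,2.5,xULN,4
Total bilirubin,≤,3,xULN,2
Serum creatinine,≤,1,xULN,6
Serum creatinine,≤,1.5,xULN,18
Serum creatinine,≤,2,xULN,5
Serum creatinine,≤,2.5,xULN,3
CrCl,≥,30,mL/min,5
CrCl,≥,40,mL/min,6
CrCl,≥,45,mL/min,8
CrCl,≥,50,mL/min,10
CrCl,≥,60,mL/min,14
Hemoglobin,≥,8,g/dL,6
Hemoglobin,≥,9,g/dL,22
Hemoglobin,≥,10,g/dL,9
Hemoglobin,≥,11,g/dL,4
ANC,≥,750,cells/uL,4
ANC,≥,1000,cells/uL,9
ANC,≥,1500,cells/uL,26
Platelets,≥,50000,cells/uL,5
Platelets,≥,75000,cells/uL,8
Platelets,≥,100000,cells/uL,25
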