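hypernym,subgroup,hyponym,value,exceptions
adequate organ function,normal hepatic function,AST,≤2.5x ULN,
adequate organ function,normal hepatic function,ALT,≤2.5x ULN,
adequate organ function,normal hepatic function,Total bilirubin,≤1.5x ULN,
adequate organ function,normal renal function,Creatinine,≤1.5x ULN,
adequate organ function,normal hematologic function,ANC,≥1500 cells/uL,
adequate organ function,normal hematologic function,Platelets,"≥100,000 cells/uL",
adequate organ function,normal hematologic function,Hemoglobin,≥9 mg/dL,
comorbidities,second malignancy,All cancers,"Yes, with exceptions",in situ cervical cancer;noninvasive bladder cancer;curative basal or squamous in situ prostate cancer;in situ breast cancer;resected skin cancer other than melanoma
comorbidities,infectious disease,HIV,Yes,
comorbidities,infectious disease,HBV,Yes,
comorbidities,infectious disease,HCV,Yes,
comorbidities,infectious disease,TB,Yes,
comorbidities,cardiovascular disease,CHF,Yes,
comorbidities,cardiovascular disease,MI,Yes,
comorbidities,cardiovascular disease,Angina,Yes,
comorbidities,cardiovascular disease,Arrhythmia,Yes,
comorbidities,autoimmune disease,UC,Yes,
comorbidities,autoimmune disease,CD,Yes,
comorbidities,autoimmune disease,Systemic lupus erythematosus,Yes,
comorbidities,autoimmune disease,Rheumatoid arthritis,Yes,
comorbidities,autoimmune disease,Systemic sclerosis,Yes,
comorbidities,autoimmune disease,Graves disease,Yes,
comorbidities,autoimmune disease,Guillain-Barré syndrome,Yes,
comorbidities,autoimmune disease,Antiphospholipid syndrome,Yes,
comorbidities,autoimmune disease,Sjogren syndrome,Yes,
biomarker,EGFR mutation sensitive to TKI,Exon 19 deletion,Yes,
biomarker,EGFR mutation sensitive to TKI,Exon 21 L858R,Yes,
biomarker,EGFR mutation sensitive to TKI,Exon 21 L861Q,Yes,
biomarker,EGFR mutation sensitive to TKI,Exon 18 G719C,Yes,
biomarker,EGFR mutation sensitive to TKI,Exon 18 G719X,Yes,
biomarker,EGFR mutation sensitive to TKI,Amplification,Yes,
biomarker,EGFR mutation resistant to TKI,Exon 20 T790M,Yes,
biomarker,EGFR mutation resistant to TKI,Exon 20 C797S,Yes,
biomarker,EGFR mutation resistant to TKI,Exon 20 S768I,Yes,
biomarker,EGFR mutation resistant to TKI,Exon 20 insertion,Yes,
biomarker,mismatch repair deficient,"MSH2, MSH6, MLH1, PMS2, or EXO1 gene mutation",Yes,
biomarker,mismatch repair deficient,MLH1 hypermethylation,Yes,
prior therapy (targeted),first-generation EGFR inhibitor,Gefitinib,Yes,
prior therapy (targeted),first-generation EGFR inhibitor,Erlotinib,Yes,
prior therapy (targeted),first-generation EGFR inhibitor,Vandetanib,Yes,
prior therapy (targeted),second-generation EGFR inhibitor,Afatinib,Yes,
prior therapy (targeted),second-generation EGFR inhibitor,Dacomitinib,Yes,
prior therapy (targeted),second-generation EGFR inhibitor,Poziotinib,Yes,
prior therapy (targeted),second-generation EGFR inhibitor,Tesevatinib,Yes,
prior therapy (targeted),third-generation EGFR inhibitor,Osimertinib,Yes,
prior therapy (targeted),third-generation EGFR inhibitor,Lazertinib,Yes,
prior therapy (targeted),third-generation EGFR inhibitor,Rociletinib,Yes,
prior therapy (targeted),third-generation EGFR inhibitor,Tarloxotinib,Yes,
prior therapy (targeted),proteasome inhibitor,Bortezomib based,Yes,
prior therapy (targeted),proteasome inhibitor,Carfilzomib based,Yes,
prior therapy (targeted),proteasome inhibitor,Ixazomib based,Yes,
prior therapy (targeted),proteasome inhibitor,Oprozomib based,Yes,
prior therapy (hormone),first-generation antiandrogen,Bicalutamide,Yes,
prior therapy (hormone),first-generation antiandrogen,Nilutamide,Yes,
prior therapy (hormone),first-generation antiandrogen,Flutamide,Yes,
prior therapy (hormone),second-generation antiandrogen,Abiraterone,Yes,
prior therapy (hormone),second-generation antiandrogen,Enzalutamide,Yes,
prior therapy (hormone),second-generation antiandrogen,Darolutamide,Yes,
prior therapy (hormone),second-generation antiandrogen,Apalutamide,Yes,
prior therapy (hormone),androgen deprivation therapy,Leuprolide,Yes,
prior therapy (hormone),androgen deprivation therapy,Goserelin,Yes,
prior therapy (hormone),androgen deprivation therapy,Degarelix,Yes,
prior therapy (hormone),5-α reducing agent,Finasteride,Yes,
prior therapy (hormone),5-α reducing agent,Dutasteride,Yes,
prior therapy (hormone),5-α reducing agent,Megestrol acetate,Yes,
other medication,current use of antibiotics,Rifabutin,Yes,
other medication,current use of antibiotics,Clarithromycin,Yes,
other medication,current use of antibiotics,Azithromycin,Yes,
other medication,current use of antibiotics,Imipenem,Yes,
other medication,current use of antiarrhythmic agents,Propafenone,Yes,
other medication,current use of antiarrhythmic agents,Procainamide,Yes,
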