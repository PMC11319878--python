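key,count
total_trials,3281
nsclc_trials,817
pca_trials,649
bca_trials,1057
mm_trials,447
uc_trials,160
cd_trials,151
annotated_trials,485
annotated_nsclc_criteria,246
ontology_design_criteria,425
pilot_cohort_patients,2775
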