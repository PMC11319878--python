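# Eligibility-criteria entity/relation schema.
# group <TAB> name <TAB> category <TAB> description
# relation <TAB> name <TAB> source_category <TAB> target_category
group	demographic	primary	Patient demographics such as age and gender
group	diagnosis	primary	Trial indication: histology, stage, diagnosis terms
group	biomarker	primary	Molecular markers and mutations (e.g. EGFR T790M)
group	disease_status	primary	Clinical status such as relapsed, refractory, progression
group	prior_therapy	primary	Previously received treatment modalities
group	comorbidity	primary	Coexisting conditions, usually exclusionary
group	laboratory_test	primary	Laboratory analytes with threshold values
group	vital	primary	Vital signs and performance scores (e.g. ECOG)
group	procedure	primary	Surgical or medical procedures
group	other_medication	primary	Concomitant or prohibited medications
group	value	modifier	Numeric or categorical limit attached to a primary entity
group	condition	modifier	Qualifying condition on a primary entity
group	evidence	modifier	Required confirmation (e.g. histologically confirmed)
group	lines_of_therapy	modifier	Count of prior treatment regimens
group	negation	modifier	Negation cue (no, without, absence of)
group	exception	modifier	Carve-out that rescues an otherwise excluded case
group	grade	modifier	Toxicity/severity grade
group	dose	modifier	Dose limit on a medication
group	temporal	modifier	Time window (e.g. within 4 weeks)
group	other_observation	other	Any entity outside the primary groups
relation	has_value_limit	primary	modifier
relation	has_temporal_limit	primary	modifier
relation	has_negation	primary	modifier
relation	has_exception	primary	modifier
relation	has_dose_limit	primary	modifier
relation	has_line_of_therapy_limit	primary	modifier
relation	has_grade_limit	primary	modifier
relation	has_condition	primary	modifier
relation	need_evidence	primary	modifier
relation	has_outcome	primary	primary
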