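# Attribute-normalization rules: rule_class <TAB> canonical <TAB> patterns (| separated).
# Matching is case-insensitive after whitespace stripping (the misc rules below).
synonym	AST	AST|SGOT|aspartate aminotransferase|serum AST
synonym	ALT	ALT|SGPT|alanine aminotransferase|serum ALT
synonym	Total bilirubin	Total bilirubin|serum bilirubin|total bilirubin level|bilirubin level
synonym	Hgb	Hgb|hemoglobin
synonym	HbA1c	HbA1c|hemoglobinA1c
synonym	Serum creatinine	serum creatinine|creatinine|creatinine levels|creatinine level
synonym	ANC	ANC|absolute neutrophil count|absolute neutrophil counts|neutrophil count|neutrophil counts|absolute neutrophil
synonym	WBC	WBC|white blood cells|white blood cell|WBC count|white blood cell count|white blood count|leucocytes
synonym	Platelets	platelets|platelet|platelet count|platelet counts
synonym	CrCl	CrCl|creatine clearance|creatinine clearance
synonym	ALP	ALP|alkaline phosphatase
synonym	ULN	ULN|upper limit of normal
synonym	LLN	LLN|lower limit of normal
comparator	≤	less than or equal to|≤
comparator	≥	greater than or equal to|≥
comparator	>	greater than|>
comparator	<	less than|<
temporal	within 4 weeks	within 4 weeks|within 28 days
temporal	within 2 weeks	within 2 weeks|within 14 days
temporal	within 3 weeks	within 3 weeks|within 21 days
temporal	within 6 months	last 6 months|past 6 months|within 6 months|within six months
temporal	within 3 months	last 3 months|past 3 months|within 3 months|within three months
temporal	within 2 years	within 2 years|last 2 years|past 2 years
temporal	within 3 years	within 3 years|last 3 years|past 3 years
temporal	within 5 years	within 5 years|last 5 years|past 5 years
unit	10^3/uL	10^9/L|10^3/uL|10^3/microliter|1000/uL|1000/microliter|K/microliter|10^3/mm^3
misc	-	case insensitive
misc	-	remove spaces
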