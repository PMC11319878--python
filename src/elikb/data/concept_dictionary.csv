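surface,canonical,cui
ER+,Estrogen receptor positive,C0279754
ER-positive,Estrogen receptor positive,C0279754
estrogen receptor-positive,Estrogen receptor positive,C0279754
estrogen receptor positive,Estrogen receptor positive,C0279754
Estrogen receptor positive,Estrogen receptor positive,C0279754
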