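protein1	protein2	combined_score
TP63	FGFR2	620
TP63	DLG1	310
FGFR2	DLG1	287
MYH3	ANKRD1	243
RGPD5	NIPBL	168
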