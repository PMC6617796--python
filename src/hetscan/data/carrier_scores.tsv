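# Reference carrier/noncarrier discrimination scores: genome-wide Stage-1
# top-% of the known (or pseudo-) dominant disease variant for 17 sequenced
# individuals from published family studies (9 carriers, 8 noncarriers).
# label: C = carrier of the pathogenic variant, N = noncarrier.
id	top_pct	label
S5	1.2	C
L22	2.9	C
S1	3.1	C
S9	4.5	C
S7	11.2	N
S6	18.1	N
M7	18.3	C
M9	20.1	C
L21	20.4	C
M1	20.7	C
Ctrl_BRCA2	22.0	N
M2	29.5	C
S2	29.8	N
Ctrl_WFS1	40.6	N
M9_NCBI3	46.9	N
M9_NCBI1	58.2	N
Ctrl_PHOX2	71.0	N
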