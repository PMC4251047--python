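protein	aa_change
KRAS	G12D
KRAS	G12V
KRAS	G12C
KRAS	G13D
KRAS	Q61H
KRAS	A146T
TP53	R175H
TP53	G245S
TP53	R248Q
TP53	R249S
TP53	R273H
TP53	R282W
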