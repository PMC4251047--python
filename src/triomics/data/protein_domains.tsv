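protein	domain	start_aa	end_aa
TP53	DNA_binding	102	292
TP53	Transactivation	1	42
TP53	Tetramerization	323	356
KRAS	RAS	5	164
KRAS	Hypervariable	167	185
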