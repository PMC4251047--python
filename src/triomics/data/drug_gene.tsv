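gene	drug	interaction_type	source
KRAS	REOLYSIN	inhibitor	DGIdb
KRAS	ANTROQUINONOL	inhibitor	DGIdb
KRAS	SELUMETINIB	pathway	DGIdb
TP53	GEMCITABINE	other	DGIdb
TP53	WEE1-INHIBITOR	synthetic lethal	DGIdb
BRAF	VEMURAFENIB	inhibitor	DGIdb
BRAF	DABRAFENIB	inhibitor	DGIdb
MYC	BET-INHIBITOR	inhibitor	DGIdb
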