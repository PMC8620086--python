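mutual14	genes mutual to all five condition networks	ADIPOQ	CRP	EDN1	EPO	GLP1R	IGF1	IL1B	IL6	INS	INSR	NFE2L2	NPY	TNF	VEGFA
endothelial_in_network	microvascular endothelial genes present in the focus network	CD36	CLDN5	EGFR	FGF2	INSR	LEP	LEPR	NOTCH1	SLC16A1	SLC22A1	SLC2A1	SLC5A1	TNF	TRAF6	VEGFA
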