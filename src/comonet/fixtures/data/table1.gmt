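hormones	molecule category	ADIPOQ	AVP	EPO	GCG	GH1	GIP	IAPP	INS	LEP	PRL	PTH	REN	SCT	SST
cytokines_growth_factors	molecule category	ANGPTL4	CCL2	CSF3	EDN1	FGF2	FGF21	IGF1	IGF2	IL1B	IL6	TNF	VEGFA
receptors	molecule category	ADRB2	ADRB3	AGTR2	CD36	CD40	EGFR	GCGR	GHRHR	GLP1R	GPR142	IGF1R	IGF2R	INSR	LEPR	MC2R	NOTCH1	NR3C1	SORCS1	SSTR2
enzymes	molecule category	ACE	AKT1	AKT2	CHAT	CPT1A	CYP2C9	CYP3A4	DNMT1	DPP4	EIF2AK3	FBP1	G6PC1	GCK	GPD1	GPD2	GPX3	GSR	GYS2	H6PD	HK1	MAP4K2	MBOAT4	METAP2	NAMPT	NOS1	PARK7	PDK4	PGM1	SERPINA1	SIAH2	SIRT1	SIRT6	SOD2	TGM1	TIGAR	UQCRC2	VHL	WWOX
transporters	molecule category	ABCC8	AQP4	AQP7	CACNA1C	KCNJ11	KCNH2	MPC2	RAMP1	SLC5A1	SLC5A2	SLC5A4	SLC16A1	SLC2A1	SLC2A2	SLC22A1	SLC30A8	SLC25A20	SLC30A10	UCP2
transcription_factors	molecule category	ARNTL	DDIT3	FOS	FOXO1	HNF1A	HNF4A	NFE2L2	NR3C1	PPARA	PROP1	SOX17	TCF7L2
neuropeptides	molecule category	ADCYAP1	CHGA	GRP	HCRT	NPY	PPY	UCN
structural_proteins	molecule category	CLDN5	MAP2
other_proteins	molecule category	ALB	CDKN1A	CISD1	CRP	IGFBP1	IGFBP2	IGFBP3	IGFBP6	NRP1	PRNP	PSMB9	PSMG1	SELE	SELP	SERPINE1	TRAF6	VAMP8
microRNAs	molecule category	MIR155	MIR410
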