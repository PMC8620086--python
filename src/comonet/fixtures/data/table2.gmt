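UP	gene expression up-regulated by hypoglycemia	ADIPOQ	ALB	ANGPTL4	AQP4	AVP	CCL2	CD40	CDKN1A	CHAT	CHGA	CRP	CYP3A4	DDIT3	EDN1	EIF2AK3	EPO	FOS	GIP	GH1	GPD1	GPX3	GRP	HCRT	IGFBP1	IGFBP2	IL6	LEPR	NOS1	NPY	PARK7	PDK4	PPY	PRL	PRNP	REN	SELE	SERPINE1	SLC2A1	SOD2	SOX17	TIGAR	VEGFA	UCN
DOWN	gene expression down-regulated by hypoglycemia	CLDN5	CPT1A	DNMT1	FBP1	GPD2	GSR	MAP2	METAP2	NFE2L2	NRP1	PTH	RAMP1	SELP	SLC25A20	SLC2A1	SST	VEGFA
CAUSAL	molecules with hypoglycemic or antihyperglycemic activity	CSF3	GIP	GLP1R	IGF1	IGF2	IGF2R	IGFBP6	IL1B	INS	KCNH2	MIR155	NOTCH1	SCT	SLC16A1	SSTR2	TRAF6
PROTECTIVE	protective effect against hypoglycemia and/or response to hypoglycemia	ADRB3	CD36	FOXO1	GCG	GCGR	DPP4	GH1	IAPP	IGFBP3	KCNH2	LEP	MBOAT4	MIR410	MPC2	PPARA	PRL	SLC2A2	SOD2	TNF	VHL	VAMP8	UCN
SNP_RISK	SNPs associated with the risk of hypoglycemia	ABCC8	ACE	ADRB2	AGTR2	AKT2	AQP7	CACNA1C	CYP2C9	G6PC	GCK	GHRHR	GYS2	HK1	HNF1A	HNF4A	IGF1R	INSR	KCNJ11	MAP4K2	MC2R	NR3C1	PGM1	PROP1	PSMB9	SERPINA1	SIRT6	SLC22A1	SLC2A2	SORCS1	TCF7L2	TGM1	UCP2	UQCRC2	WWOX
OTHER	other links	ADCYAP1	AKT1	ARNTL	CISD1	EGFR	FGF2	FGF21	GPR142	H6PD	NAMPT	PSMG1	SIAH2	SIRT1	SLC2A2	SLC30A10	SLC30A8	SLC5A1	SLC5A2	SLC5A4
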