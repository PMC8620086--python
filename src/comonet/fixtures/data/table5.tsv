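row_class	col_class	genes
UP	UP	CCL2;CD40;CDKN1A;CYP3A4;FOS;HCRT;IGFBP2;IL6;PARK7;SERPINA1;VEGFA
UP	DOWN	AVP;EDN1;LEPR;SLC2A1;VEGFA
UP	SNP_RISK	CHAT;NPY;PRNP
UP	OTHER	ADIPOQ;ALB;AQP4;CHGA;CRP;DDIT3;EIF2AK3;EPO;GH1;GIP;NOS1;SERPINE1;SOD2
DOWN	UP	VEGFA
DOWN	DOWN	MAP2;METAP2;NFE2L2;SELP;SST;VEGFA
DOWN	SNP_RISK	DNMT1
SNP_RISK	UP	CYP2C9
SNP_RISK	DOWN	HK1;IGF1R;INSR;NR3C1;SIRT6;WWOX
SNP_RISK	SNP_RISK	ADRB2;PSMB9
SNP_RISK	OTHER	ACE;IGF2R;PGM1;SORCS1;TCF7L2
OTHER	UP	IGF2;IGFBP3;MIR155;NOTCH1;TNF
OTHER	DOWN	NAMPT;SIRT1;SLC30A10;SSTR2
OTHER	SNP_RISK	AKT1;ARNTL;CD36;IL1B;PPARA
OTHER	OTHER	ADCYAP1;CSF3;EGFR;FGF2;FOXO1;GLP1R;IAPP;IGF1;INS;KCNH2;LEP;SLC16A1
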