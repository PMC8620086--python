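{
  "top_cts": ["GPR142", "MBOAT4", "SLC5A4", "IGFBP6", "PPY", "G6PC1", "SLC2A2", "GYS2", "GCGR", "AQP7"],
  "hub_genes": ["INS", "IL6", "LEP", "TNF", "IL1B", "EGFR", "FOS"]
}
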