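alias	canonical
G6PC	G6PC1
GLUT2	SLC2A2
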