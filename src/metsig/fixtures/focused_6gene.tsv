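gene_symbol	log2_fc
CHIT1	2.86
DNMT1	1.0
GPD1	-1.13
PLA2G4A	-1.77
TARSL2	-1.1
SETD7	-1.12
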