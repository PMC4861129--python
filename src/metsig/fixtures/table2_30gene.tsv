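gene_symbol	log2_fc
XDH	4.28
TDO2	3.73
GAD1	2.88
CHIT1	2.86
DNMT3B	2.54
PYCR1	2.53
KMO	1.83
TYMP	1.52
PYCRL	1.45
SUV420H2	1.2
B4GALT3	1.14
LYPLA2	1.08
PLA2G15	1.08
DNMT1	1.0
NNMT	-1.01
BST1	-1.05
TARSL2	-1.1
SETD7	-1.12
GPD1	-1.13
GPD1L	-1.19
EXTL1	-1.32
GATM	-1.33
GAMT	-1.43
ALDH7A1	-1.64
DPYD	-1.66
ALDH1B1	-1.76
PLA2G4A	-1.77
PIPOX	-1.96
ALDH2	-2.37
INMT	-2.61
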