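# SYNTHETIC demo metabolite -> gene map for examples and smoke tests only.
# Hand-assembled illustrative enzyme assignments for the differential
# metabolite classes of the bladder-cancer study; NOT an authoritative
# KEGG mapping and not used by any statistical validation.
tryptophan	TDO2
tryptophan	KMO
kynurenine	KMO
3-hydroxykynurenine	KMO
SAH	DNMT1
SAH	DNMT3B
SAM	DNMT1
SAM	DNMT3B
SAM	NNMT
S-ribosyl-homocysteine	LYPLA2
methionine	DNMT1
methionine	GAMT
cystathionine	GAMT
sarcosine	GATM
sarcosine	GAMT
sarcosine	PIPOX
asparagine	GAD1
homoserine	GATM
threonine	ALDH7A1
NAD	NNMT
NAD	BST1
nicotinamide	NNMT
xanthine	XDH
thymine	TYMP
thymine	DPYD
acetyl-lysine	SUV420H2
acetyl-lysine	SETD7
UDP-acetyl-glucosamine	B4GALT3
acetyl-glutamine	EXTL1
acetyl-butyric-acid	ALDH2
valine	ALDH1B1
glycyl-leucine	TARSL2
proline	PYCR1
proline	PYCRL
4-coumarate	ALDH2
tyrosine	INMT
2-aminobutyraldehyde	ALDH7A1
propionyl-carnitine	GPD1
4-aminobutyrate	ALDH2
4-aminobutyrate	GPD1L
glycerol-3-phosphate	GPD1
glycerol-3-phosphate	GPD1L
arachidonate	PLA2G4A
arachidonate	PLA2G15
chitotriose	CHIT1
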