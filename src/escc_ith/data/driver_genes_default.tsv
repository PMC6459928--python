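gene	recessive
TP53	1
NOTCH1	1
CDKN2A	1
PIK3CA	0
KMT2D	1
ZNF750	1
ERBB4	0
EGFR	0
FGFR1	0
CCND1	0
MYC	0
CDK6	0
RB1	1
PTCH1	1
CREBBP	1
MET	0
MTOR	0
AXIN2	1
NFE2L2	0
FAT1	1
FAT2	1
AJUBA	1
KDM6A	1
EP300	1
TGFBR2	1
BRCA1	1
BRCA2	1
PTEN	1
SMAD4	1
ARID1A	1
NOTCH2	1
NOTCH3	1
SOX2	0
CUL3	1
RASA1	1
KEAP1	1
FBXW7	1
HRAS	0
KRAS	0
CDK4	0
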