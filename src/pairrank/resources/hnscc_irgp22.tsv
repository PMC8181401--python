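gene_a	gene_b	coefficient
WNT5A	STC1	-0.416040
HLA-DOB	VEGFC	-0.220430
LTB4R	HBEGF	-0.172370
SPINK5	NAMPT	-0.136800
DEFB1	HBEGF	-0.071100
CD1A	DKK1	-0.063380
SPINK5	IRF7	-0.057520
SPINK5	STC2	-0.007870
THBS1	CXCL9	0.036130
FABP4	VCAM1	0.074010
APOD	CD79A	0.079920
DKK1	NR4A2	0.094100
STC2	NR1H3	0.110600
HLA-DOB	CD79A	0.122560
DKK1	IL24	0.129490
APOD	VCAM1	0.129540
DKK1	GHR	0.130360
CXCL1	DEFB1	0.163580
OASL	CD79A	0.211550
CXCL1	CCL5	0.212470
FABP4	PDGFRA	0.216210
APOD	CD247	0.425300
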