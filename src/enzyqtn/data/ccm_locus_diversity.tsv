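# Published per-locus nucleotide diversity (pi) for 17 maize central-carbon-
# metabolism loci sequenced in a diverse maize inbred panel (n=28) and a
# teosinte panel (n=16), with the maize/teosinte ratio and its percent tail
# in a reference distribution of 774 random genes.
locus	pi_maize	pi_teosinte	ratio	percent_tail
Ald	0.0010	0.0066	0.1451	14
eno2	0.0001	0.0009	0.1474	14
Scoal	0.0011	0.0069	0.1560	14
Fum	0.0041	0.0079	0.5186	36
Idh	0.0032	0.0058	0.5466	38
g6pdh	0.0072	0.0106	0.6766	51
eno	0.0095	0.0118	0.8071	64
hex	0.0087	0.0107	0.8161	64
pgam	0.0049	0.0058	0.8495	68
pgm	0.0108	0.0126	0.8608	69
sdh	0.0052	0.0054	0.9527	76
mdh	0.0087	0.0083	1.0560	82
Ald2	0.0095	0.0083	1.1392	87
pgk	0.0092	0.0078	1.1829	89
aco	0.0051	0.0039	1.2811	91
pgm2	0.0092	0.0063	1.4655	93
ogdh	0.0040	0.0026	1.5768	94
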