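gene	family	chrom	pos	nucleotide	aa_change	dbsnp	maf	cadd	carriers	total
DAAM2	191	6	39861001	A>G	Tyr128Cys	rs201047462	0.00017	28.00	2	2
DAAM2	716	6	39884013	C>T	Arg680Trp	rs200964833	0.00019	35.00	3	3
MKL2	1893	16	14245640	T>C	Ser398Pro	rs113935526	0.00479	19.20	3	3
MKL2	26044	16	14245640	T>C	Ser398Pro	rs113935526	0.00479	19.20	2	3
PLEKHG5	803	1	6496525	G>A	Pro40Ser	rs201669114	0.00148	27.00	2	2
PLEKHG5	1008	1	6496525	G>A	Pro40Ser	rs201669114	0.00148	27.00	2	2
THBS2	1240	6	169220312	C>A	Val1133Phe	rs112533700	0.00017	29.50	2	2
THBS2	1893	6	169220312	C>A	Val1133Phe	rs112533700	0.00017	29.50	3	3
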