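family	carriers	lod	gene	chrom	pos	nucleotide	aa_change	dbsnp	maf	cadd
757	9	2.95	CD163L1	12	7369477	T>C	Thr1317Ala	rs150384982	0.00137	3.73
757	9	2.95	CLECL1	12	9722727	T>C	Thr135Ala	rs118152239	0.00769	0.03
911	7	2.36	CTNNA1	5	138824559	G>C	Gln206His	rs150893072	0.0043	23.2
1201	5	2.22	GALR3	22	37823563	C>G	Pro53Ala	rs78650836	0.00328	10.31
1201	5	2.22	MIEF1	22	39512414	C>T	Arg169Trp	rs2232088	0.00525	34
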