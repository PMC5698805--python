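gene	chrom	pos	nucleotide	aa_change	dbsnp	maf	cadd	family	carriers	total
AKAP9	7	92002147	G>A	Glu756Lys	rs202091548	0.00008	27.8	191	1	2
AKAP9	7	92017092	G>A	Arg1288Gln	rs146797353	0.00822	6.2	419	2	2
CD33	19	51225851	CCCGG>C	Gly210Thrfs*2	rs201074739	0.01339	-	2349	1	2
CR1	1	207618089	A>G	Lys2308Arg	rs41274770	0.01463	11.9	1893	2	3
EPHA1	7	143398060	C>T	Arg492Gln	rs11768549	0.01214	17.39	701	1	3
INPP5D	2	233125865	G>A	Arg157Gln	rs200834931	0.00139	17.75	1399	2	2
INPP5D	2	233206711	C>A	Ala994Asp	rs187622749	0.00433	22.8	2349	2	2
NME8	7	37884315	G>A	Arg336His	rs62001869	0.01436	6.08	1893	3	3
PSEN1	14	73206470	A>G	Glu318Gly	rs17125721	0.01423	16.92	419	1	2
SORL1	11	121543625	C>T	Thr588Ile	rs752726649	0.00001	32	191	2	2
SORL1	11	121627591	C>T	Thr2134Met	rs142884576	0.00023	28.6	1240	1	2
TREM2	6	41161469	C>T	Arg92His	rs143332484	0.00791	11.11	1893	1	3
UNC5C	4	95170263	C>T	Ala860Thr	rs34585936	0.01808	33	191	2	2
UNC5C	4	95170263	C>T	Ala860Thr	rs34585936	0.01808	33	2119	1	2
UNC5C	4	95202928	G>A	Pro666Ser	rs760453427	0.00001	20.2	191	1	2
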