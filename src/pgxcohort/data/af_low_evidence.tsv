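chrom	pos	rsid	gene	ref	alt	af_study	af_ref
1	207753621	rs2274567	CR1	A	G	0.608	0.195
6	31093482	rs3131003	PSORS1C1	G	A	0.739	0.432
6	31093587	rs3815087	PSORS1C1	G	A	0.507	0.217
12	13953118	rs2058878	GRIN2B	G	A	0.602	0.338
12	85243681	rs6539870	IL1B	A	G	0.486	0.221
3	45732515	rs2742421	SACM1L	A	G	0.687	0.427
6	31603770	rs11229	PRRC2A	A	G	0.435	0.176
15	30193316	rs813676	TJP1	T	C	0.761	0.504
6	31107361	rs2233945	PSORS1C1	C	A	0.417	0.163
6	31604591	rs10885	PRRC2A	C	T	0.436	0.182
6	31018546	rs2523864	HCG22	C	T	0.679	0.433
19	15959200	rs2189784	CYP4F2	G	A	0.667	0.423
6	31022113	rs3873352	HCG22	T	G	0.336	0.091
6	43737794	rs13207351	VEGFA	A	G	0.611	0.367
3	151090996	rs9859552	P2RY12	G	T	0.338	0.094
6	31543101	rs361525	TNF	G	A	0.292	0.054
6	31542308	rs1799964	TNF	T	C	0.447	0.214
6	78173281	rs130058	HTR1B	G	A	0.414	0.183
5	158750769	rs3213094	IL12B	C	T	0.427	0.206
7	86331756	rs2189814	GRM3	T	C	0.375	0.159
10	32202069	rs2799018	ARHGAP12	C	T	0.611	0.396
10	92619161	rs7905446	HTR7	A	G	0.480	0.276
6	33047612	rs3097671	HLA-DPB1	T	C	0.366	0.163
1	29161999	rs2236855	OPRD1	G	A	0.386	0.185
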