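chrom	pos	rsid	gene	ref	alt	af_study	af_ref
1	161514542	rs396991	FCGR3A	A	C	0.528	0.317
16	31104509	rs8050894	VKORC1	T	G	0.523	0.374
19	15990431	rs2108622	CYP4F2	C	T	0.415	0.294
16	31107689	rs9923231	VKORC1	C	T	0.510	0.392
16	31104878	rs9934438	VKORC1	G	A	0.510	0.395
6	39325078	rs20455	KIF6	A	G	0.463	0.364
1	11856378	rs1801133	MTHFR	G	A	0.424	0.349
16	31105554	rs2884737	VKORC1	A	C	0.353	0.278
1	97981395	rs1801159	DPYD	T	C	0.252	0.199
1	98348885	rs1801265	DPYD	A	G	0.159	0.215
21	46957794	rs1051266	SLC19A1	T	C	0.511	0.568
6	31543031	rs1800629	TNF	G	A	0.050	0.159
16	31103796	rs2359612	VKORC1	A	G	0.490	0.604
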