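gene	allele	is_reference	chrom	pos	rsid	ref	alt	required_allele
CFTR	Reference	1
CFTR	F508del	0	7	117559590	rs113993960	CTT	C	C
CFTR	G551D	0	7	117587806	rs75527207	G	A	A
CYP2B6	*1	1
CYP2B6	*4	0	19	41515263	rs2279343	A	G	G
CYP2B6	*6	0	19	41512841	rs3745274	G	T	T
CYP2C19	*1	1
CYP2C19	*2	0	10	94781859	rs4244285	G	A	A
CYP2C19	*17	0	10	94761900	rs12248560	C	T	T
CYP2C9	*1	1
CYP2C9	*2	0	10	94942290	rs1799853	C	T	T
CYP2C9	*3	0	10	94981296	rs1057910	A	C	C
CYP2D6	*1	1
CYP2D6	*4	0	22	42128945	rs3892097	C	T	T
CYP3A5	*1	1
CYP3A5	*3	0	7	99270539	rs776746	T	C	C
CYP4F2	*1	1
CYP4F2	*2	0	19	15990292	rs3093105	A	C	C
CYP4F2	*3	0	19	15990431	rs2108622	C	T	T
DPYD	*1	1
DPYD	*2A	0	1	97915614	rs3918290	C	T	T
IFNL3	rs12979860C	1
IFNL3	rs12979860T	0	19	39738787	rs12979860	C	T	T
NUDT15	*1	1
NUDT15	*3	0	13	48037782	rs116855232	C	T	T
SLCO1B1	*1A	1
SLCO1B1	*1B	0	12	21329738	rs2306283	A	G	G
SLCO1B1	*5	0	12	21331549	rs4149056	T	C	C
SLCO1B1	*15	0	12	21329738	rs2306283	A	G	G
SLCO1B1	*15	0	12	21331549	rs4149056	T	C	C
TPMT	*1	1
TPMT	*2	0	6	18139228	rs1800462	C	G	G
TPMT	*3C	0	6	18130918	rs1142345	T	C	C
UGT1A1	*1	1
UGT1A1	*80	0	2	234668570	rs887829	C	T	T
VKORC1	-1639G	1
VKORC1	-1639A	0	16	31107689	rs9923231	G	A	A
VKORC1	-1639A	0	16	31104878	rs9934438	C	T	T
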