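annotation_id	rsid	gene	evidence_level	phenotype_category	drugs	pediatric
1184661194	rs2108622	CYP4F2	2A	Dosage	acenocoumarol	0
981204044	rs9923231	VKORC1	1A	Dosage	acenocoumarol	0
1183704228	rs9934438	VKORC1	2A	Dosage	acenocoumarol	0
1451237940	rs9923231	VKORC1	1A	Dosage	phenprocoumon	1
1451244040	rs9934438	VKORC1	2A	Dosage	phenprocoumon	1
655385400	rs2108622	CYP4F2	1A	Dosage	warfarin	1
982035703	rs2884737	VKORC1	2A	Dosage	warfarin	0
655385392	rs9934438	VKORC1	1B	Dosage	warfarin	1
655385028	rs8050894	VKORC1	1B	Dosage	warfarin	0
655385012	rs9923231	VKORC1	1A	Dosage	warfarin	1
655385024	rs2359612	VKORC1	1B	Dosage	warfarin	0
655384799	rs1800629	TNF	2B	Efficacy	etanercept	0
1451245360	rs1051266	SLC19A1	2A	Efficacy	methotrexate	0
655384621	rs20455	KIF6	2B	Efficacy	pravastatin	0
1444608384	rs396991	FCGR3A	2B	Efficacy	rituximab	0
1447672998	rs9923231	VKORC1	2A	Efficacy	warfarin	1
1447673015	rs9923231	VKORC1	2A	Efficacy	warfarin	1
1451286320	rs1801159	DPYD	1A	Toxicity	capecitabine	0
1451287240	rs1801265	DPYD	1A	Toxicity	capecitabine	0
981201981	rs1801265	DPYD	1A	Toxicity	fluorouracil	1
981201962	rs1801159	DPYD	1A	Toxicity	fluorouracil	0
827848365	rs1801133	MTHFR	2A	Toxicity	methotrexate	1
655385307	rs1801133	MTHFR	2A	Toxicity	methotrexate	1
1451243676	rs9923231	VKORC1	2A	Toxicity	phenprocoumon	0
1449269910	rs9923231	VKORC1	2A	Toxicity	warfarin	1
1447673005	rs9923231	VKORC1	1B	Toxicity	warfarin	1
900000001	rs2274567	CR1	3	Efficacy	immunoglobulins	0
900000002	rs3131003	PSORS1C1	4	Toxicity	allopurinol	0
900000003	rs3815087	PSORS1C1	3	Toxicity	allopurinol	0
900000004	rs2058878	GRIN2B	3	Efficacy	ketamine	0
900000005	rs6539870	IL1B	3	Efficacy	adalimumab	0
900000006	rs2742421	SACM1L	3	Toxicity	nevirapine	0
900000007	rs11229	PRRC2A	3	Toxicity	aspirin	0
900000008	rs813676	TJP1	3	Efficacy	metformin	0
900000009	rs2233945	PSORS1C1	3	Efficacy	etanercept	0
900000010	rs10885	PRRC2A	3	Toxicity	aspirin	0
900000011	rs2523864	HCG22	3	Toxicity	carbamazepine	0
900000012	rs2189784	CYP4F2	3	Dosage	warfarin	0
900000013	rs3873352	HCG22	3	Toxicity	carbamazepine	0
900000014	rs13207351	VEGFA	3	Efficacy	bevacizumab	0
900000015	rs9859552	P2RY12	3	Efficacy	clopidogrel	0
900000016	rs361525	TNF	3	Efficacy	etanercept	0
900000017	rs1799964	TNF	3	Efficacy	infliximab	0
900000018	rs130058	HTR1B	3	Efficacy	sumatriptan	0
900000019	rs3213094	IL12B	3	Efficacy	ustekinumab	0
900000020	rs2189814	GRM3	3	Efficacy	risperidone	0
900000021	rs2799018	ARHGAP12	3	Efficacy	citalopram	0
900000022	rs7905446	HTR7	3	Efficacy	risperidone	0
900000023	rs3097671	HLA-DPB1	3	Toxicity	aspirin	0
900000024	rs2236855	OPRD1	3	Efficacy	opioids	0
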