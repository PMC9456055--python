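gene	phenotype	count
CFTR	Ivacaftor irrelevant	1555
CFTR	Ivacaftor non-responsive	14
CFTR	Ivacaftor responsive	8
CYP2B6	Indeterminate	50
CYP2B6	Intermediate Metabolizer	552
CYP2B6	Normal Metabolizer	862
CYP2B6	Not available	8
CYP2B6	Poor Metabolizer	85
CYP2B6	Rapid Metabolizer	20
CYP2C19	Intermediate Metabolizer	450
CYP2C19	Normal Metabolizer	715
CYP2C19	Poor Metabolizer	32
CYP2C19	Rapid Metabolizer	343
CYP2C19	Ultrarapid Metabolizer	37
CYP2C9	Intermediate Metabolizer	606
CYP2C9	Normal Metabolizer	925
CYP2C9	Not available	2
CYP2C9	Poor Metabolizer	44
CYP2D6	Indeterminate	207
CYP2D6	Normal Metabolizer	622
CYP2D6	Not available	748
CYP3A5	Intermediate Metabolizer	304
CYP3A5	Normal Metabolizer	16
CYP3A5	Not available	14
CYP3A5	Poor Metabolizer	1243
CYP4F2	Increased dose phenotype	268
CYP4F2	Indeterminate	11
CYP4F2	Normal dose phenotype	534
CYP4F2	Not available	764
DPYD	Intermediate Metabolizer	117
DPYD	Normal Metabolizer	1460
IFNL3	Favorable response genotype	721
IFNL3	Unfavorable response genotype	856
NUDT15	Intermediate Metabolizer	2
NUDT15	Normal Metabolizer	1575
SLCO1B1	Decreased Function	324
SLCO1B1	Indeterminate	133
SLCO1B1	Normal Function	533
SLCO1B1	Not available	201
SLCO1B1	Poor Function	51
SLCO1B1	Possible increased function	335
TPMT	Indeterminate	2
TPMT	Intermediate Function	101
TPMT	Normal Function	1472
TPMT	Poor Function	2
UGT1A1	Normal Metabolizer	815
UGT1A1	Not available	762
VKORC1	Decreased warfarin dose	414
VKORC1	Normal warfarin dose	385
VKORC1	Possibly decreased warfarin dose	778
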