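gene	phenotype	nontypical
CFTR	Ivacaftor irrelevant	0
CFTR	Ivacaftor responsive	0
CFTR	Ivacaftor non-responsive	1
CYP2B6	Normal Metabolizer	0
CYP2B6	Intermediate Metabolizer	1
CYP2B6	Poor Metabolizer	1
CYP2B6	Rapid Metabolizer	1
CYP2B6	Ultrarapid Metabolizer	1
CYP2C19	Normal Metabolizer	0
CYP2C19	Intermediate Metabolizer	1
CYP2C19	Poor Metabolizer	1
CYP2C19	Rapid Metabolizer	1
CYP2C19	Ultrarapid Metabolizer	1
CYP2C19	Likely Intermediate Metabolizer	1
CYP2C19	Likely Poor Metabolizer	1
CYP2C9	Normal Metabolizer	0
CYP2C9	Intermediate Metabolizer	1
CYP2C9	Poor Metabolizer	1
CYP2D6	Normal Metabolizer	0
CYP2D6	Intermediate Metabolizer	0
CYP2D6	Poor Metabolizer	0
CYP3A5	Normal Metabolizer	0
CYP3A5	Intermediate Metabolizer	1
CYP3A5	Poor Metabolizer	1
CYP4F2	Normal dose phenotype	0
CYP4F2	Increased dose phenotype	1
DPYD	Normal Metabolizer	0
DPYD	Intermediate Metabolizer	1
DPYD	Poor Metabolizer	1
IFNL3	Favorable response genotype	0
IFNL3	Unfavorable response genotype	1
NUDT15	Normal Metabolizer	0
NUDT15	Intermediate Metabolizer	0
NUDT15	Possible Intermediate Metabolizer	0
NUDT15	Poor Metabolizer	1
SLCO1B1	Normal Function	0
SLCO1B1	Possible increased function	0
SLCO1B1	Possible Increased Function	0
SLCO1B1	Possible Decreased Function	0
SLCO1B1	Possible Poor Function	1
SLCO1B1	Decreased Function	1
SLCO1B1	Poor Function	1
TPMT	Normal Function	0
TPMT	Intermediate Function	1
TPMT	Poor Function	1
TPMT	Possible Intermediate Metabolizer	0
UGT1A1	Normal Metabolizer	0
UGT1A1	Intermediate Metabolizer	1
UGT1A1	Poor Metabolizer	1
VKORC1	Normal warfarin dose	0
VKORC1	Possibly decreased warfarin dose	1
VKORC1	Decreased warfarin dose	1
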