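gene	allele1	allele2	phenotype
CFTR	Reference	Reference	Ivacaftor irrelevant
CFTR	Reference	F508del	Ivacaftor irrelevant
CFTR	F508del	F508del	Ivacaftor non-responsive
CFTR	Reference	G551D	Ivacaftor responsive
CFTR	G551D	G551D	Ivacaftor responsive
CFTR	F508del	G551D	Ivacaftor responsive
CYP2B6	*1	*1	Normal Metabolizer
CYP2B6	*1	*6	Intermediate Metabolizer
CYP2B6	*6	*6	Poor Metabolizer
CYP2B6	*1	*4	Normal Metabolizer
CYP2B6	*4	*4	Rapid Metabolizer
CYP2B6	*4	*6	Intermediate Metabolizer
CYP2C19	*1	*1	Normal Metabolizer
CYP2C19	*1	*2	Intermediate Metabolizer
CYP2C19	*2	*2	Poor Metabolizer
CYP2C19	*1	*17	Rapid Metabolizer
CYP2C19	*17	*17	Ultrarapid Metabolizer
CYP2C19	*17	*2	Intermediate Metabolizer
CYP2C9	*1	*1	Normal Metabolizer
CYP2C9	*1	*2	Intermediate Metabolizer
CYP2C9	*1	*3	Intermediate Metabolizer
CYP2C9	*2	*2	Intermediate Metabolizer
CYP2C9	*2	*3	Poor Metabolizer
CYP2C9	*3	*3	Poor Metabolizer
CYP2D6	*1	*1	Normal Metabolizer
CYP2D6	*1	*4	Indeterminate
CYP2D6	*4	*4	Indeterminate
CYP3A5	*1	*1	Normal Metabolizer
CYP3A5	*1	*3	Intermediate Metabolizer
CYP3A5	*3	*3	Poor Metabolizer
CYP4F2	*1	*1	Normal dose phenotype
CYP4F2	*1	*3	Normal dose phenotype
CYP4F2	*3	*3	Increased dose phenotype
CYP4F2	*1	*2	Indeterminate
CYP4F2	*2	*2	Indeterminate
CYP4F2	*2	*3	Indeterminate
DPYD	*1	*1	Normal Metabolizer
DPYD	*1	*2A	Intermediate Metabolizer
DPYD	*2A	*2A	Poor Metabolizer
IFNL3	rs12979860C	rs12979860C	Favorable response genotype
IFNL3	rs12979860C	rs12979860T	Unfavorable response genotype
IFNL3	rs12979860T	rs12979860T	Unfavorable response genotype
NUDT15	*1	*1	Normal Metabolizer
NUDT15	*1	*3	Intermediate Metabolizer
NUDT15	*3	*3	Poor Metabolizer
SLCO1B1	*1A	*1A	Normal Function
SLCO1B1	*1A	*1B	Normal Function
SLCO1B1	*1B	*1B	Possible increased function
SLCO1B1	*1A	*5	Decreased Function
SLCO1B1	*1B	*5	Decreased Function
SLCO1B1	*15	*1A	Decreased Function
SLCO1B1	*15	*1B	Decreased Function
SLCO1B1	*5	*5	Poor Function
SLCO1B1	*15	*5	Poor Function
SLCO1B1	*15	*15	Poor Function
TPMT	*1	*1	Normal Function
TPMT	*1	*2	Intermediate Function
TPMT	*1	*3C	Intermediate Function
TPMT	*2	*2	Poor Function
TPMT	*2	*3C	Poor Function
TPMT	*3C	*3C	Poor Function
UGT1A1	*1	*1	Normal Metabolizer
UGT1A1	*1	*80	Intermediate Metabolizer
UGT1A1	*80	*80	Poor Metabolizer
VKORC1	-1639G	-1639G	Normal warfarin dose
VKORC1	-1639A	-1639G	Possibly decreased warfarin dose
VKORC1	-1639A	-1639A	Decreased warfarin dose
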