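gene	allele	frequency
CFTR	Reference	0.930
CFTR	F508del	0.065
CFTR	G551D	0.005
CYP2B6	*1	0.700
CYP2B6	*6	0.250
CYP2B6	*4	0.050
CYP2C19	*1	0.620
CYP2C19	*2	0.150
CYP2C19	*17	0.230
CYP2C9	*1	0.790
CYP2C9	*2	0.130
CYP2C9	*3	0.080
CYP2D6	*1	0.800
CYP2D6	*4	0.200
CYP3A5	*1	0.080
CYP3A5	*3	0.920
CYP4F2	*1	0.550
CYP4F2	*3	0.420
CYP4F2	*2	0.030
DPYD	*1	0.960
DPYD	*2A	0.040
IFNL3	rs12979860C	0.680
IFNL3	rs12979860T	0.320
NUDT15	*1	0.999
NUDT15	*3	0.001
SLCO1B1	*1A	0.450
SLCO1B1	*1B	0.300
SLCO1B1	*5	0.150
SLCO1B1	*15	0.100
TPMT	*1	0.955
TPMT	*3C	0.040
TPMT	*2	0.005
UGT1A1	*1	0.700
UGT1A1	*80	0.300
VKORC1	-1639G	0.491
VKORC1	-1639A	0.509
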