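gene	drug	cpic_level
CFTR	ivacaftor	A
CYP2B6	efavirenz	A
CYP2C19	amitriptyline	A
CYP2C19	citalopram	A
CYP2C19	sertraline	A
CYP2C19	clopidogrel	A
CYP2C19	escitalopram	A
CYP2C19	imipramine	A
CYP2C19	clomipramine	A
CYP2C19	doxepin	A
CYP2C19	trimipramine	A
CYP2C19	voriconazole	A
CYP2C9	ibuprofen	A
CYP2C9	piroxicam	A
CYP2C9	celecoxib	A
CYP2C9	meloxicam	A
CYP2C9	phenytoin	A
CYP2C9	flurbiprofen	A
CYP2C9	tenoxicam	A
CYP2C9	lornoxicam	A
CYP2C9	warfarin	A
CYP2D6	codeine	A
CYP2D6	tramadol	A
CYP2D6	tamoxifen	A
CYP3A5	tacrolimus	A
CYP4F2	warfarin	A
DPYD	fluorouracil	A
DPYD	capecitabine	A
IFNL3	ribavirin	A
IFNL3	peginterferon alfa-2a	A
IFNL3	peginterferon alfa-2b	A
NUDT15	azathioprine	A
NUDT15	mercaptopurine	A
NUDT15	thioguanine	A
SLCO1B1	fluvastatin	A
SLCO1B1	lovastatin	A
SLCO1B1	pitavastatin	A
SLCO1B1	pravastatin	A
SLCO1B1	rosuvastatin	A
SLCO1B1	simvastatin	A
TPMT	azathioprine	A
TPMT	mercaptopurine	A
TPMT	thioguanine	A
UGT1A1	atazanavir	A
UGT1A1	irinotecan	A
VKORC1	warfarin	A
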