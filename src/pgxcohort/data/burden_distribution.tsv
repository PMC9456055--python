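n_individuals	n_drugs
1	39
3	38
6	37
12	36
16	35
14	34
5	33
7	32
5	31
19	30
38	29
57	28
47	27
49	26
40	25
45	24
43	23
51	22
36	21
34	20
42	19
92	18
132	17
125	16
127	15
89	14
58	13
58	12
22	11
22	10
12	9
11	8
2	7
9	6
27	5
49	4
68	3
55	2
40	1
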