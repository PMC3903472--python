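patient	sample	age	sex	stage	location	differentiation	msi	aberration_count
1	3T	51	F	3	L	Well	MSS	462
2	4T	55	F	1	R	Moderately	MSI-H	6
3	8T	46	M	3	L	Well	MSS	13
4	9T	63	M	3	L	Well	MSS	1
5	12T	40	M	1	L	Well	MSI-L	139
6	16T	58	F	2	L	Well	MSS	17
7	18T	45	M	2	L	Well	MSS	57
8	22T	60	M	2	L	Well	MSI-L	374
9	25T	72	M	2	L	Well	MSS	147
10	28T	60	M	2	L	Well	MSS	18
11	29T	65	M	2	L	Well	MSI-H	55
12	31T	47	F	1	R	Moderately	MSI-H	10
13	32T	70	M	3	R	Poorly	MSI-H	7
14	35T	81	M	1	L	Well	MSS	154
15	36T	78	F	3	L	Moderately	MSS	43
16	38T	81	M	1	R	Well	MSS	244
17	40T	54	M	3	L	Moderately	MSS	66
18	42T	68	F	1	L	Well	MSS	31
19	44T	28	F	2	L	Well	MSI-L	827
20	46T	57	F	2	R	Moderately	MSI-H	13
21	47T	63	F	2	L	Moderately	MSS	12
22	49T	40	F	2	L	Well	MSI-L	37
23	53T	70	M	3	L	Moderately	MSS	9
24	58T	70	M	3	L	Moderately	MSS	30
25	71T	67	M	2	L	Moderately	MSS	67
26	72T	60	M	2	L	Moderately	MSS	91
27	77T	55	F	2	L	Well	MSS	5
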