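drug	block	category	count	pct
anakinra	age_group	<18	956	12.67
anakinra	age_group	18–40	829	10.99
anakinra	age_group	40–60	1128	14.95
anakinra	age_group	60–80	875	11.60
anakinra	age_group	≥80	92	1.22
anakinra	age_group	unknown	3664	48.57
anakinra	sex	Female	4878	64.66
anakinra	sex	Male	2482	32.90
anakinra	sex	unknown	184	2.44
anakinra	reporter	Consumer	4988	66.12
anakinra	reporter	Physician	1196	15.85
anakinra	reporter	Pharmacist	564	7.48
anakinra	reporter	Other health-professional	428	5.67
anakinra	reporter	unknown	358	4.75
anakinra	reporter	Registered nurse	8	0.11
anakinra	reporter	Lawyer	2	0.03
anakinra	route	Subcutaneous	5480	72.64
anakinra	route	Others	1970	26.11
anakinra	route	Intravenous	53	0.70
anakinra	route	Transplacental	41	0.54
anakinra	outcomes	Other serious	2280	49.54
anakinra	outcomes	Hospitalization	1628	35.38
anakinra	outcomes	Death	486	10.56
anakinra	outcomes	Life threatening	122	2.65
anakinra	outcomes	Disability	49	1.06
anakinra	outcomes	Congenital anomaly	24	0.52
anakinra	outcomes	Required intervention	13	0.28
anakinra	tto	<30	1827	32.74
anakinra	tto	30–180	241	4.32
anakinra	tto	180–360	85	1.52
anakinra	tto	360–540	60	1.08
anakinra	tto	≥540	251	4.50
anakinra	tto	unknown	3116	55.84
canakinumab	age_group	<18	2008	24.96
canakinumab	age_group	18–40	766	9.52
canakinumab	age_group	40–60	650	8.08
canakinumab	age_group	60–80	670	8.33
canakinumab	age_group	≥80	80	0.99
canakinumab	age_group	unknown	3870	48.11
canakinumab	sex	Female	4273	53.12
canakinumab	sex	Male	3052	37.94
canakinumab	sex	unknown	719	8.94
canakinumab	reporter	Consumer	3611	44.89
canakinumab	reporter	Physician	2076	25.81
canakinumab	reporter	Pharmacist	1524	18.95
canakinumab	reporter	Other health-professional	767	9.54
canakinumab	reporter	unknown	63	0.78
canakinumab	reporter	Registered nurse	3	0.04
canakinumab	reporter	Lawyer	0	0.00
canakinumab	route	Subcutaneous	5570	69.24
canakinumab	route	Others	2350	29.21
canakinumab	route	Intravenous	67	0.83
canakinumab	route	Transplacental	14	0.17
canakinumab	route	Intramuscular	26	0.32
canakinumab	route	Oral	17	0.21
canakinumab	outcomes	Other serious	2147	44.94
canakinumab	outcomes	Hospitalization	1929	40.38
canakinumab	outcomes	Death	368	7.70
canakinumab	outcomes	Life threatening	263	5.51
canakinumab	outcomes	Disability	62	1.30
canakinumab	outcomes	Congenital anomaly	7	0.15
canakinumab	outcomes	Required intervention	1	0.02
canakinumab	tto	<30	567	14.33
canakinumab	tto	30–180	637	16.09
canakinumab	tto	180–360	344	8.69
canakinumab	tto	360–540	223	5.63
canakinumab	tto	≥540	707	17.86
canakinumab	tto	unknown	1480	37.39
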