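drug	soc	pt	n	ror	ror_lo95	ror_hi95	prr	prr_lo95	prr_hi95	chisq	ic	ic025	ebgm	ebgm05
anakinra	General disorders and administration site conditions	Injection site pain	895	6.55	6.13	7.01	6.38	6.02	6.77	4067.63	2.67	2.57	6.36	6.02
anakinra	General disorders and administration site conditions	Injection site erythema	614	10.18	9.4	11.03	9.99	9.24	10.8	4947.28	3.31	3.2	9.93	9.29
anakinra	General disorders and administration site conditions	Pyrexia	485	2.78	2.54	3.04	2.75	2.49	3.03	542.07	1.46	1.33	2.75	2.55
anakinra	General disorders and administration site conditions	Injection site pruritus	470	14.56	13.29	15.96	14.34	13	15.82	5791.58	3.83	3.7	14.23	13.18
anakinra	General disorders and administration site conditions	Condition aggravated	409	2.92	2.64	3.22	2.89	2.62	3.19	506.9	1.53	1.39	2.89	2.66
anakinra	General disorders and administration site conditions	Injection site reaction	399	11.84	10.72	13.07	11.69	10.6	12.89	3877.24	3.54	3.39	11.61	10.69
anakinra	General disorders and administration site conditions	Injection site urticaria	296	26.79	23.87	30.06	26.52	23.58	29.83	7159.53	4.71	4.54	26.13	23.72
anakinra	General disorders and administration site conditions	Injection site rash	287	20.66	18.38	23.23	20.47	18.2	23.02	5252.54	4.34	4.17	20.23	18.35
anakinra	General disorders and administration site conditions	Injection site swelling	283	7.95	7.07	8.94	7.88	7.01	8.86	1693.99	2.97	2.8	7.85	7.11
anakinra	Infections and infestations	Infection	274	3.97	3.52	4.47	3.94	3.5	4.43	601.6	1.98	1.8	3.93	3.56
anakinra	General disorders and administration site conditions	Injection site bruising	272	7.28	6.46	8.2	7.22	6.42	8.12	1452.51	2.85	2.67	7.19	6.51
anakinra	Skin and subcutaneous tissue disorders	Urticaria	215	2.68	2.34	3.06	2.67	2.33	3.06	223.96	1.41	1.22	2.66	2.38
anakinra	General disorders and administration site conditions	Illness	163	4.77	4.09	5.56	4.75	4.06	5.56	481.1	2.24	2.02	4.74	4.16
anakinra	Infections and infestations	Sinusitis	155	3.02	2.58	3.54	3.01	2.57	3.52	207.9	1.59	1.36	3.01	2.63
anakinra	Injury, poisoning and procedural complications	Contusion	146	3.04	2.58	3.57	3.02	2.58	3.53	197.88	1.6	1.36	3.02	2.64
anakinra	Infections and infestations	Influenza	125	2.42	2.03	2.88	2.41	2.02	2.87	103.2	1.27	1.02	2.41	2.08
anakinra	General disorders and administration site conditions	Injection site mass	124	7.01	5.87	8.36	6.98	5.85	8.33	633.47	2.8	2.54	6.96	6
anakinra	General disorders and administration site conditions	Swelling	177	2.53	2.11	3.04	2.53	2.12	3.02	107.99	1.34	1.08	2.52	2.17
anakinra	General disorders and administration site conditions	Injection site warmth	109	10.04	8.31	12.13	10.01	8.23	12.18	878.73	3.32	3.04	9.95	8.5
anakinra	Infections and infestations	Cellulitis	98	3.74	3.07	4.56	3.73	3.07	4.54	195.46	1.9	1.61	3.72	3.15
canakinumab	General disorders and administration site conditions	Pyrexia	1232	8.35	7.89	8.84	8.01	7.55	8.5	7563.18	3	2.91	7.97	7.6
canakinumab	General disorders and administration site conditions	Malaise	669	3.18	2.94	3.43	3.12	2.88	3.37	972.39	1.64	1.53	3.12	2.93
canakinumab	General disorders and administration site conditions	Condition aggravated	620	4.92	4.54	5.33	4.83	4.47	5.22	1885.01	2.27	2.15	4.82	4.51
canakinumab	Musculoskeletal and connective tissue disorders	Arthralgia	480	2.55	2.33	2.79	2.52	2.28	2.78	442.3	1.33	1.2	2.52	2.33
canakinumab	Skin and subcutaneous tissue disorders	Rash	434	2.27	2.06	2.5	2.25	2.04	2.48	302.79	1.17	1.03	2.25	2.08
canakinumab	Respiratory, thoracic and mediastinal disorders	Cough	289	2.27	2.02	2.54	2.25	2	2.53	201.81	1.17	1	2.25	2.04
canakinumab	Gastrointestinal disorders	Abdominal pain	235	2.28	2.01	2.6	2.27	2.02	2.55	167.94	1.18	1	2.27	2.04
canakinumab	General disorders and administration site conditions	Illness	230	6.59	5.78	7.5	6.54	5.7	7.5	1076.18	2.7	2.52	6.52	5.84
canakinumab	Infections and infestations	Nasopharyngitis	226	2.62	2.3	2.99	2.61	2.28	2.99	223.95	1.38	1.19	2.6	2.33
canakinumab	Infections and infestations	Influenza	176	3.54	3.05	4.1	3.52	3.01	4.12	317.71	1.81	1.6	3.52	3.11
canakinumab	Infections and infestations	Infection	152	2.33	1.99	2.74	2.33	1.99	2.73	115.11	1.22	0.99	2.32	2.03
canakinumab	Respiratory, thoracic and mediastinal disorders	Oropharyngeal pain	141	3.14	2.66	3.71	3.13	2.68	3.66	204.52	1.64	1.41	3.13	2.72
canakinumab	Musculoskeletal and connective tissue disorders	Joint swelling	139	2.49	2.11	2.94	2.48	2.12	2.9	122.88	1.31	1.07	2.48	2.16
canakinumab	Respiratory, thoracic and mediastinal disorders	Rhinorrhoea	134	4.51	3.8	5.34	4.49	3.76	5.36	362.92	2.16	1.92	4.48	3.89
canakinumab	Investigations	C-reactive protein increased	131	8.57	7.22	10.18	8.53	7.15	10.18	867.28	3.09	2.84	8.49	7.36
canakinumab	Musculoskeletal and connective tissue disorders	Arthritis	119	3.21	2.68	3.84	3.2	2.68	3.82	179.6	1.67	1.42	3.19	2.75
canakinumab	General disorders and administration site conditions	Inflammation	107	4.84	4	5.85	4.82	3.96	5.86	323.4	2.27	1.99	4.81	4.1
canakinumab	Infections and infestations	Cellulitis	88	3.74	3.03	4.61	3.73	3.01	4.63	175.64	1.9	1.6	3.72	3.13
canakinumab	Respiratory, thoracic and mediastinal disorders	Nasal congestion	84	3.18	2.57	3.95	3.18	2.56	3.95	125.23	1.67	1.36	3.17	2.65
canakinumab	Blood and lymphatic system disorders	Lymphadenopathy	79	5.12	4.1	6.38	5.1	4.11	6.33	260.04	2.35	2.03	5.09	4.23
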