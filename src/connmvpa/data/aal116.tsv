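id	name	lobe	hemisphere
1	PreCG.L	frontal	L
2	PreCG.R	frontal	R
3	SFGdor.L	frontal	L
4	SFGdor.R	frontal	R
5	ORBsup.L	frontal	L
6	ORBsup.R	frontal	R
7	MFG.L	frontal	L
8	MFG.R	frontal	R
9	ORBmid.L	frontal	L
10	ORBmid.R	frontal	R
11	IFGoperc.L	frontal	L
12	IFGoperc.R	frontal	R
13	IFGtriang.L	frontal	L
14	IFGtriang.R	frontal	R
15	ORBinf.L	frontal	L
16	ORBinf.R	frontal	R
17	ROL.L	frontal	L
18	ROL.R	frontal	R
19	SMA.L	frontal	L
20	SMA.R	frontal	R
21	OLF.L	frontal	L
22	OLF.R	frontal	R
23	SFGmed.L	frontal	L
24	SFGmed.R	frontal	R
25	ORBsupmed.L	frontal	L
26	ORBsupmed.R	frontal	R
27	REC.L	frontal	L
28	REC.R	frontal	R
29	INS.L	limbic	L
30	INS.R	limbic	R
31	ACG.L	limbic	L
32	ACG.R	limbic	R
33	DCG.L	limbic	L
34	DCG.R	limbic	R
35	PCG.L	limbic	L
36	PCG.R	limbic	R
37	HIP.L	limbic	L
38	HIP.R	limbic	R
39	PHG.L	limbic	L
40	PHG.R	limbic	R
41	AMYG.L	limbic	L
42	AMYG.R	limbic	R
43	CAL.L	occipital	L
44	CAL.R	occipital	R
45	CUN.L	occipital	L
46	CUN.R	occipital	R
47	LING.L	occipital	L
48	LING.R	occipital	R
49	SOG.L	occipital	L
50	SOG.R	occipital	R
51	MOG.L	occipital	L
52	MOG.R	occipital	R
53	IOG.L	occipital	L
54	IOG.R	occipital	R
55	FFG.L	limbic	L
56	FFG.R	limbic	R
57	PoCG.L	parietal	L
58	PoCG.R	parietal	R
59	SPG.L	parietal	L
60	SPG.R	parietal	R
61	IPL.L	parietal	L
62	IPL.R	parietal	R
63	SMG.L	parietal	L
64	SMG.R	parietal	R
65	ANG.L	parietal	L
66	ANG.R	parietal	R
67	PCUN.L	parietal	L
68	PCUN.R	parietal	R
69	PCL.L	parietal	L
70	PCL.R	parietal	R
71	CAU.L	subcortical	L
72	CAU.R	subcortical	R
73	PUT.L	subcortical	L
74	PUT.R	subcortical	R
75	PAL.L	subcortical	L
76	PAL.R	subcortical	R
77	THA.L	subcortical	L
78	THA.R	subcortical	R
79	HES.L	temporal	L
80	HES.R	temporal	R
81	STG.L	temporal	L
82	STG.R	temporal	R
83	TPOsup.L	temporal	L
84	TPOsup.R	temporal	R
85	MTG.L	temporal	L
86	MTG.R	temporal	R
87	TPOmid.L	temporal	L
88	TPOmid.R	temporal	R
89	ITG.L	temporal	L
90	ITG.R	temporal	R
91	CRBLCrus1.L	cerebellum	L
92	CRBLCrus1.R	cerebellum	R
93	CRBLCrus2.L	cerebellum	L
94	CRBLCrus2.R	cerebellum	R
95	CRBL3.L	cerebellum	L
96	CRBL3.R	cerebellum	R
97	CRBL45.L	cerebellum	L
98	CRBL45.R	cerebellum	R
99	CRBL6.L	cerebellum	L
100	CRBL6.R	cerebellum	R
101	CRBL7b.L	cerebellum	L
102	CRBL7b.R	cerebellum	R
103	CRBL8.L	cerebellum	L
104	CRBL8.R	cerebellum	R
105	CRBL9.L	cerebellum	L
106	CRBL9.R	cerebellum	R
107	CRBL10.L	cerebellum	L
108	CRBL10.R	cerebellum	R
109	Vermis12	vermis	M
110	Vermis3	vermis	M
111	Vermis45	vermis	M
112	Vermis6	vermis	M
113	Vermis7	vermis	M
114	Vermis8	vermis	M
115	Vermis9	vermis	M
116	Vermis10	vermis	M
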