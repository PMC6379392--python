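case_id	sanger	deep_seq	effect	outcome	genomic_profile	age_months	inrg
1	Not done	Neg		NED > 5 y	Other segm.	18	L
2	Neg	Neg		DOD	NMA	27	M
3	Neg	Neg		DOD	11q-del	76	L
4	Not done	Neg		NED > 5 y	17q-gain	14	L
5	Neg	Neg		NED > 5 y	17q-gain	102	L
6	Not done	Neg		NED > 5 y	Num only	32	L
7	Neg	Neg		NED > 5 y	Other segm.	12	L
8	Neg	D1160D	Neg	NED > 5 y	Num only	21	L
9	Neg	Neg		DOD	NMA	19	M
10	Neg	Neg		DOD	Num only	48	M
11	Not done	Neg		NED > 5 y	11q-del	30	L
12	F1174L	F1174L (24,7%)	GOF	DOD	NMA	15	M
13	Neg	Neg		NED > 5 y	Num only	30	L
14	Neg	Neg		NED > 5 y	17q-gain	19	L
15	Neg	Neg		DOD	11q-del	80	L
16	Neg	Neg		DOD	NMA	18	M
17	F1174C	F1174C (19%)	GOF	NED > 5 y	Num only	25	L
18	Neg	I1171T (2,7%)	GOF	NED > 5 y	NMA	29	M
19	Neg	Neg		DOD	NMA	37	L
20	Neg	Neg		NED > 5 y	Other segm.	21	L
21	Neg	Neg		NED > 5 y	11q-del	9	L
22	Neg	Neg		DOD	11q-del	80	M
23	Neg	Neg		DOD	NMA	8	L
24	Neg	Neg		NED > 5 y	NMA	35	L
25	Neg	Neg		NED > 5 y	Num only	43	L
26	F1245I	F1245I (53%)	GOF	AWD	Other segm.	5	L
27	Neg	Neg		NED > 5 y	Num only	0	L
28	Neg	Neg		DOD	NMA	21	M
29	Neg	Neg		NED > 5 y	11q-del	74	M
30	Neg	Neg		DOD	11q-del	6	M
31	Neg	Neg		NED > 5 y	11q-del	43	M
32	Neg	Neg		DOD	17q-gain	10	L
33	Not done	Neg		NED > 5 y	Other segm.	12	L
34	Neg	Neg		DOD	11q-del	170	L
35	Neg	Neg		DOD	NMA	37	M
36	Neg	Neg		NED > 5 y	Other segm.	4	L
37	Neg	Neg		NED > 5 y	Other segm.	63	L
38	F1245C	F1245C (52,4%)	GOF	NED > 5 y	17q-gain	92	M
39	Neg	Neg		NED > 5 y	Num only	11	L
40	1st Neg/2nd F1147S	2nd F1174S (58,7%) and F1174I (7,7%)	GOF & GOF	DOD	17q-gain	12	M
41	Not done	Neg		NED > 5 y	17q-gain	6	L
42	F1174I	F1174I (22%)	GOF	NED > 5 y	Other segm.	27	L
43	F1174L	F1174L (22%)	GOF	NED > 5 y	Other segm.	90	M
44	Neg	Neg		DOD	NMA	12	M
45	Not done	Amp.		DOD	NMA ( + ALK-amp)	11	M
46	Neg	Neg		DOD	Other segm.	33	M
47	Neg	F1245I (14%)	GOF	DOD	NMA	21	M
48	Neg	Neg		DOD	17q-gain	55	M
49	Not done	Neg		NED > 5 y	NMA	15	M
50	1st Neg /2nd F1174L	F1174L (25,9%)	GOF	DOD	NMA	29	M
51	Not done	Neg		NED > 5 y	11q-del	33	M
52	Neg	Neg		DOD	11q-del	32	M
53	F1174I, const.	F1174I (61,2%)	GOF	DOD	Other segm.	1	M
54	Neg	Neg		DOD	Num only	0	MS
55	Neg	Neg		DOD	11q-del	21	M
56	Neg	Neg		DOD	NMA	14	M
57	Neg	Amp.		DOD	NMA ( + ALK-amp)	31	M
58	Not done	Neg		NED > 5 y	11q-del	10	L
59	Not done	Neg		NED > 5 y	17q gain	98	L
60	Neg	Amp.		DOD	NMA ( + ALK-amp)	25	M
61	F1174L	F1174L (18%)	GOF	DOD	NMA	41	L
62	Neg	Neg		NED > 5 y	11q-del	92	M
63	Not done	Neg		NED < 5 y	Other segm.	6	L
64	Neg	Neg		NED < 5 y	Other segm.	5	L
65	Not done	Neg		NED < 5 y	NMA	28	M
66	Not done	Neg		NED < 5 y	Other segm.	32	L
67	Not done	Neg		NED < 5 y	Num only	2	L
68	Not done	Neg		NED < 5 y	17q gain	37	L
69	Not done	Neg		DOD	NMA	39	M
70	Neg	Neg		DOD	NMA + 11q-del	28	M
71	Not done	Neg		NED < 5 y	NMA	18	L
72	Neg	Neg		NED < 5 y	11q-del	18	L
73	Not done	Neg		NED < 5 y	11q-del	26	L
74	Not done	Neg		NED < 5 y	Other segm.	11	M
75	Neg	Neg		NED < 5 y	11q-del	70	L
76	Not done	Neg		NED < 5 y	Num only	1	L
77	Not done	Neg		NED < 5 y	Num only	18	L
78	Neg	Neg		NED < 5 y	Other segm.	0	L
79	Neg	Neg		DOD	NMA + 11q-del	30	M
80	Neg	Neg		NED < 5 y	Other segm.	37	L
81	Neg	Neg		NED < 5 y	NMA	13	L
82	Neg	Neg		NED < 5 y	NMA	10	L
83	Neg	Neg		NED < 5 y	11q-del	18	L
84	Neg	F1174L (15,1%)	GOF	NED < 5 y	NMA	23	M
85	Neg	Neg		NED < 5 y	Num only	6	L
86	Neg	Neg		NED < 5 y	11q-del	158	M
87	Neg	Neg		NED < 5 y	Other segm.	12	L
88	Neg	Neg		NED < 5 y	NMA	33	M
89	Neg	Amp.		NED < 5 y	NMA ( + ALK-amp)	39	M
90	Neg	Neg		NED < 5 y	Num only	2	L
91	Neg	Neg		DOD	NMA + 11q-del	11	M
92	Neg	F1174L (14%)	GOF	NED < 5 y	17q gain	37	L
93	Neg	Neg		NED < 5 y	11q-del	124	L
94	Neg	Neg		NED < 5 y	11q-del	51	L
95	Neg	Neg		NED < 5 y	11q-del	13	L
96	Neg	Neg		NED < 5 y	11q-del	29	L
97	F1174L	F1174L (22,1%)	GOF	NED < 5 y	NUM only	8	L
98	Neg	Neg		NED < 5 y	11q-del	50	M
99	L1240V	L1240V (57,4%)	GOF	DOD	17q gain + chrom.tr	44	M
100	Not done	Neg		NED < 5 y	Other segm.	2	L
101	Not done	Neg		NED < 5 y	NMA	27	L
102	Not done	Neg		NED < 5 y	17q-gain	66	M
103	Not done	Neg		NED < 5 y	Num only	8	L
104	Not done	Neg		NED < 5 y	NMA	15	L
105	Not done	Neg		AWD	NMA	37	M
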