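no	cultivar	grain	total_reads	aligned_reads	sequenced_mb	snps	snps_per_100kb
1	Colusa	short	8909990	8355240	16.7	861	5.2
2	Caloro	short	5571659	5110290	10.2	610	6.0
3	Calrose	medium	6418466	6234660	12.5	1887	15.1
4	CS-M3	medium	6313437	5741670	11.5	1910	16.6
5	CS-S4	short	4157417	4111110	8.2	498	6.1
6	M5	medium	9117640	8406930	16.8	2733	16.3
7	S6	short	6459490	5966973	11.9	1429	12.0
8	Calrose76	medium	5772255	5473152	10.9	1417	12.9
9	M7	medium	3090181	2893575	5.8	777	13.4
10	M9	medium	4389869	4324590	8.6	1859	21.5
11	Calmochi-201	short	2977348	2799468	5.6	541	9.7
12	L-201	long	8248291	7832565	15.7	7422	47.4
13	M-101	medium	7284788	6607359	13.2	1756	13.3
14	M-301	medium	6928960	6401370	12.8	2017	15.8
15	S-201	short	8730052	8398140	16.8	2095	12.5
16	Calmochi-202	short	4122284	3840480	7.7	768	10.0
17	M-302	medium	7000246	6561687	13.1	2132	16.2
18	M-401	medium	3637833	3322450	6.6	835	12.6
19	M-201	medium	2091366	1963395	3.9	721	18.4
20	L-202	long	2165942	1974560	3.9	877	22.2
21	Calmochi-101	short	1898160	1772280	3.5	215	6.1
22	M-202	medium	2359219	2131800	4.3	542	12.7
23	A-301	long	4734314	4260360	8.5	2932	34.4
24	M-102	medium	6961247	6444620	12.9	2700	20.9
25	M-203	medium	4919289	4527200	9.1	1531	16.9
26	S-101	short	4457206	4263336	8.5	1639	19.2
27	M-103	medium	2136715	2070880	4.1	268	6.5
28	S-301	short	2083500	2006825	4.0	394	9.8
29	L-203	long	2208945	2029374	4.1	990	24.4
30	M-204	medium	5056909	4868400	9.7	2505	25.7
31	A-201	long	8538074	7685760	15.4	6776	44.1
32	L-204	long	3954634	3545600	7.1	1569	22.1
33	S-102	short	4590403	4337830	8.7	1132	13.0
34	Calhikari-201	short	3801227	3641190	7.3	856	11.8
35	Calmati-201	long	3367693	3300425	6.6	2276	34.5
36	L-205	long	954074	921403	1.8	206	11.2
37	M-402	medium	2162900	1948150	3.9	483	12.4
38	M-104	medium	2976145	2897160	5.8	904	15.6
39	M-205	medium	2343036	2270268	4.5	448	9.9
40	M-206	medium	5476784	5189895	10.4	2092	20.2
41	M-207	medium	4194550	3859123	7.7	1378	17.9
42	Calamylow-201	short	3879058	3592160	7.2	840	11.7
43	Calmati-202	long	1891807	1700250	3.4	512	15.1
44	L-206	long	4566763	4270805	8.5	2746	32.1
45	M-208	medium	5430022	5211900	10.4	1635	15.7
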