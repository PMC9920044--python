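qtl	overlaps	trait	chrom	peak_marker	peak_cm	peak_mb	lod	left_cm	right_cm	left_mb	right_mb	pve	add
qLA1_1a	qLA2_1a,qLA3_1a	LA1	1	M1_1166	32.795	48.337	4.83	30.017	37.881	43.581	59.421	5.10	1.58
qLA1_1b	qLA2_1b,qLA3_1b	LA1	1	M1_2435	61.082	198.272	15.13	59.686	63.862	197.395	201.738	11.15	2.88
qLA1_2a	qLA2_2a,qFLA_2a,qTBA_2a	LA1	2	M2_233	8.021	4.278	14.32	5.830	9.181	3.550	4.643	12.11	3.45
qLA1_2b	qLA2_2b,qLA3_2b	LA1	2	M2_1194	41.982	56.798	24.25	40.358	43.482	49.336	63.033	12.31	3.85
qLA1_2c	qLA3_2c	LA1	2	M2_3360	81.294	239.246	3.15	77.133	89.575	232.638	240.608	2.49	1.14
qLA1_3a		LA1	3	M3_1035	29.584	112.427	9.74	27.168	30.504	28.624	124.132	8.57	-2.63
qLA1_3b	qLA2_3b,qLA3_3b	LA1	3	M3_2745	71.527	221.433	3.38	56.828	83.324	199.396	232.901	1.14	-0.82
qLA1_8a		LA1	8	M8_92	4.033	2.674	3.42	0.329	10.579	0.329	5.567	1.20	1.35
qLA1_8b	qLA2_8,qLA3_8	LA1	8	M8_2408	58.637	172.527	3.36	55.855	69.779	170.455	177.712	2.96	1.71
qLA1_9a		LA1	9	M9_204	16.823	12.891	3.53	9.518	26.843	8.655	23.397	1.98	-0.99
qLA1_9b		LA1	9	M9_1140	36.426	122.524	4.17	33.416	40.704	116.939	136.756	1.89	-1.28
qLA1_10	qLA2_10,qLA3_10	LA1	10	M10_1122	33.420	125.573	5.94	30.773	34.804	110.756	129.677	3.55	-1.96
qLA2_1a	qLA1_1a,qLA3_1a	LA2	1	M1_1171	33.141	48.957	4.65	29.211	37.881	40.599	59.421	6.33	1.82
qLA2_1b	qLA1_1b,qLA3_1b	LA2	1	M1_2419	59.108	197.050	11.03	54.252	61.888	184.642	199.718	7.80	2.73
qLA2_2a	qLA1_2a,qFLA_2a,qTBA_2a	LA2	2	M2_224	7.328	4.157	7.19	6.407	8.601	3.763	4.552	14.18	4.26
qLA2_2b	qLA1_2b,qLA3_2b	LA2	2	M2_1366	43.942	92.168	14.57	41.174	45.227	50.706	103.717	12.12	4.38
qLA2_3a	qLA3_3a	LA2	3	M3_1499	35.920	160.130	11.77	34.999	36.958	157.122	162.370	9.14	-3.20
qLA2_3b	qLA1_3b,qLA3_3b	LA2	3	M3_2764	72.450	221.909	3.31	68.294	85.290	217.463	234.083	2.16	-1.50
qLA2_8	qLA1_8b,qLA3_8	LA2	8	M8_2389	57.715	171.912	4.86	55.855	66.649	170.455	176.434	2.93	1.89
qLA2_10	qLA1_10,qLA3_10	LA2	10	M10_1121	33.420	125.573	4.28	30.773	38.624	110.756	134.519	2.49	-1.75
qLA3_1a	qLA1_1a,qLA2_1a	LA3	1	M1_1166	32.795	48.337	3.81	29.787	38.686	42.457	62.466	5.87	1.74
qLA3_1b	qLA1_1b,qLA2_1b	LA3	1	M1_2435	61.082	198.272	9.24	59.686	63.862	197.395	201.738	7.55	2.77
qLA3_2a		LA3	2	M2_129	4.558	2.802	5.91	0.385	5.830	1.334	3.419	11.74	4.03
qLA3_2b	qLA1_2b,qLA2_2b	LA3	2	M2_1194	41.982	56.798	10.86	39.663	45.227	48.215	103.717	11.20	4.06
qLA3_2c	qLA1_2c	LA3	2	M2_3360	81.294	239.246	3.97	78.860	89.575	235.987	240.608	3.81	1.83
qLA3_3a	qLA2_3a	LA3	3	M3_1500	35.920	160.130	8.98	34.654	38.227	156.318	168.871	6.80	-2.82
qLA3_3b	qLA1_3b,qLA2_3b	LA3	3	M3_2764	72.450	221.909	3.43	66.906	84.022	215.395	233.055	1.62	-1.43
qLA3_8	qLA1_8b,qLA2_8	LA3	8	M8_2444	60.836	174.152	3.74	55.855	69.779	170.455	177.712	2.79	1.90
qLA3_10	qLA1_10,qLA2_10	LA3	10	M10_1199	36.421	132.104	3.42	30.773	43.697	110.756	138.708	1.36	-1.35
qFLA_2a	qLA1_2a,qLA2_2a,qTBA_2a	FLA	2	M2_235	8.021	4.280	24.10	7.328	9.181	4.157	4.643	21.08	5.67
qFLA_2b		FLA	2	M2_2116	54.368	192.027	5.10	50.759	56.454	187.006	194.259	4.35	2.50
qFLA_4		FLA	4	M4_2580	66.584	241.604	3.77	62.652	70.067	238.274	242.881	3.11	2.03
qFLA_5a		FLA	5	M5_3058	62.087	202.984	6.07	56.661	63.813	182.116	210.045	2.65	3.01
qFLA_5b		FLA	5	M5_3747	82.921	219.988	11.52	80.145	85.962	219.017	220.891	8.75	-3.78
qFLA_8		FLA	8	M8_281	14.880	9.191	5.26	12.659	19.438	7.207	12.515	4.39	2.56
qTBA_1a		TBA	1	M1_764	22.958	30.613	3.38	18.091	30.017	19.586	43.581	0.85	3.35
qTBA_1b		TBA	1	M1_2052	49.527	160.088	9.26	48.607	54.022	117.695	182.705	8.83	-6.86
qTBA_1c		TBA	1	M1_3954	90.487	280.610	3.36	88.409	95.226	277.727	288.355	1.86	-3.17
qTBA_2a	qLA1_2a,qLA2_2a,qFLA_2a	TBA	2	M2_249	9.411	4.808	12.83	8.601	11.393	4.606	5.715	14.23	7.57
qTBA_2b		TBA	2	M2_1806	48.338	174.019	12.90	45.227	49.607	103.988	183.652	8.93	6.48
qTBA_3a		TBA	3	M3_443	23.480	16.956	6.00	20.086	24.979	11.691	20.883	6.95	4.91
qTBA_3b		TBA	3	M3_2361	57.633	203.076	12.56	56.253	58.668	198.496	206.503	9.25	6.70
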