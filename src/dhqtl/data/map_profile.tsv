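chrom	n_snps	mean_mb	max_mb	length_cm	mean_cm	max_cm
1	4529	0.068	15.603	114.39	0.025	1.174
2	3276	0.075	10.891	110.28	0.034	4.788
3	2954	0.080	8.111	86.10	0.029	1.782
4	2661	0.093	17.568	74.45	0.028	2.532
5	3730	0.060	4.081	89.08	0.024	1.782
6	1864	0.093	12.173	71.68	0.038	2.660
7	1500	0.121	13.779	85.96	0.057	8.851
8	2644	0.068	5.863	74.29	0.028	1.659
9	1986	0.080	13.308	67.94	0.034	2.030
10	1773	0.085	7.159	59.77	0.033	2.532
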