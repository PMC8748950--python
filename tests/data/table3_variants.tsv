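Chr	Pos	Gene	ExonicFunc	Polyphen2_HDIV_score	CADD_phred	SIFT_score	ExAC_ALL	DP	QUAL	QD	FS
1	32164127	COL16A1	nonsynonymous SNV	1	14	0	0.002	50	200	8	5
7	36656035	AOAH	nonsynonymous SNV	1	21	0.01	0.1172	50	200	8	5
9	133769023	QRFP	nonsynonymous SNV	0.999	18	0	0.0043	50	200	8	5
10	97144031	SORBS1	nonsynonymous SNV	1	17	0.01	0.0007	50	200	8	5
11	108098576	ATM	nonsynonymous SNV	0.98	18	0	0.0074	50	200	8	5
12	114837349	TBX5	nonsynonymous SNV	1	23	0	0.0034	50	200	8	5
16	71571658	CHST4	nonsynonymous SNV	0.999	17	0.02	0.0033	50	200	8	5
19	50747534	MYH14	nonsynonymous SNV	1	15	0	0.0029	50	200	8	5
20	61485507	TCFL5	nonsynonymous SNV	1	16	0	0.0028	50	200	8	5
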