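timepoint	rank	gene	accession	fold_change	utr5_sites	cds_sites	utr3_sites
12	1	TGFBR2	NM_001024847	-2.0	0	0	3
12	2	DAZAP2	NM_014764	-1.9	0	0	1
12	3	MICA	NM_000247	-1.8	1	0	1
12	4	TBC1D2	NM_018421	-1.8	0	0	1
24	1	IL6	NM_000600	-2.1	0	0	0
24	2	JAK1	NM_002227	-2.0	0	2	2
24	3	RNH1	NM_203385	-1.9	0	0	2
24	4	HDHD1A	NM_012080	-1.9	0	0	3
24	5	C9orf152	NM_001012993	-1.9	0	0	0
24	6	DAZAP2	NM_014764	-1.9	0	0	1
24	7	TGFBR2	NM_001024847	-1.9	0	0	3
24	8	TBC1D2	NM_018421	-1.9	0	0	1
24	9	MT2A	NM_005953	-1.8	0	0	0
48	1	IL6	NM_000600	-3.4	0	0	0
48	2	KRT17	NM_000422	-2.1	0	0	0
48	3	C1QTNF1	NM_198594	-2.0	1	0	0
48	4	C8orf4	NM_020130	-2.0	0	0	1
48	5	CYR61	NM_001554	-1.9	0	0	0
48	6	S100P	NM_005980	-1.9	0	0	0
48	7	CCL20	NM_004591	-1.9	0	0	0
48	8	IRAK2	NM_001570	-1.8	0	0	1
48	9	SLC16A6	NM_004694	-1.8	0	0	2
48	10	HSF2BP	NM_007031	-1.8	0	1	0
48	11	ALDH1A3	NM_000693	1.8	0	0	1
48	12	CLCA2	NM_006536	1.9	0	0	1
48	13	SLC1A3	NM_004172	1.9	0	1	2
48	14	OLFML1	NM_198474	1.9	0	1	0
48	15	KRTHB1	NM_002281	1.9	0	0	1
48	16	KRT86	NM_002284	1.9	0	0	0
48	17	ACTA2	NM_001613	2.1	1	0	1
48	18	TAC3	NM_001006667	3.7	0	0	0
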