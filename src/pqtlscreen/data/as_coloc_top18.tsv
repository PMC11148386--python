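Protein	N_SNPs	PPH0	PPH1	PPH2	PPH3	PPH4
AGER	3712	5.72E-127	0.0539114	7.44E-112	0.942793077	0.00329552
AIF1	3856	5.32E-96	0.00167447	6.92E-74	0.102649734	0.8956758
ATF6B	5359	0	2.76E-06	0	0.112731838	0.8872654
C4A	6478	1.23E-87	0.12798836	1.60E-35	0.867830945	0.004180694
CFB	4550	0	5.65E-32	0	1	9.20E-63
CLIC1	5123	4.51E-85	0.00515944	5.86E-58	0.994758254	8.23E-05
COL11A2	4456	0	6.27E-06	0	0.264638428	0.7353553
ERAP1	5769	1.66E-294	0.00557209	2.16E-175	0.994095938	0.000331968
HLA-DQA2	5345	9.30E-103	0.01197295	1.21E-85	0.9835284	0.004498653
HSPA1L	5837	2.44E-57	0.00249477	3.17E-73	0.254142326	0.7433629
IL23R	4234	0	7.37E-79	0	1	3.22E-45
LILRB3	5967	6.23E-134	0.06756285	8.10E-141	0.918001065	0.01443609
MAPK14	4345	0	2.00E-07	0	0.022823	0.9771768
MICA	3487	6.32E-36	2.75E-05	8.22E-64	0.144419507	0.855553
MICB	6498	4.68E-63	0.13818637	6.08E-74	0.849662271	0.01215136
MPIG6B	4543	0	0.00280414	0	0.996948415	0.000247442
TNXB	5349	0	4.98E-09	0	0.735989895	0.2640101
VARS1	4591	9.52E-48	0.86206095	1.24E-52	0.038984424	0.09895463
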