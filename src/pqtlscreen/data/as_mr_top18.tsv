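id.exposure	b	se	P-val	or	or_lci95	or_uci95
IL23R	0.910738095	0.17152	1.10E-07	2.486156877	1.776346799	3.479599828
ATF6B	0.790523956	0.100935112	4.80E-15	2.204551213	1.808849735	2.686815801
C4A	0.318389759	0.039770145	1.19E-15	1.374912042	1.271808972	1.486373476
COL11A2	0.302283909	0.070992156	2.06E-05	1.352945285	1.177200641	1.554926901
TNXB	0.288305453	0.066304125	1.37E-05	1.334164767	1.171575435	1.519317981
LILRB3	0.142045886	0.035405812	6.02E-05	1.152629536	1.075354628	1.235457414
ERAP1	0.132335882	0.025460529	2.02E-07	1.141491661	1.085926181	1.199900357
MICB	-0.361808092	0.049643729	3.14E-13	0.696416003	0.631845864	0.76758475
CFB	-0.36645838	0.072386049	4.14E-07	0.693184987	0.601496215	0.79885029
HLA-DQA2	-0.450084251	0.046000788	1.32E-22	0.637574433	0.582605033	0.697730254
AGER	-0.549864917	0.063904962	7.67E-18	0.577027752	0.509096017	0.654024026
MICA	-0.596719252	0.024205555	3.49E-134	0.550615106	0.525102321	0.577367463
MAPK14	-0.906780645	0.183013878	7.24E-07	0.40382218	0.28210164	0.578062408
AIF1	-1.081463415	0.097452654	1.29E-28	0.33909892	0.280138651	0.410468449
CLIC1	-1.893118036	0.274137029	4.99E-12	0.150601495	0.087999283	0.257738581
VARS1	-2.370585134	0.297909331	1.76E-15	0.093426043	0.052105362	0.167514922
HSPA1L	-2.424102426	0.304649057	1.76E-15	0.08855757	0.048741982	0.160897096
MPIG6B	-3.59552822	0.92036903	9.36E-05	0.027446182	0.004519059	0.166692427
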