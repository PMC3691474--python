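gene	cluster	locus_1	locus_2	S	N	dS	dN	omega_printed	ts_printed	tn_printed
MarR regulator	betTABI	CPS_4007	CPS_1337	110	335	2.68	0.27	0.10	294	605
hypothetical	betTABI	CPS_4008	CPS_1336	159	540	2.58	0.26	0.10	283	572
betT	betTABI	CPS_4009	CPS_1335	328	887	3.72	0.13	0.03	409	281
betA	betTABI	CPS_4010	CPS_1334	385	1295	2.18	0.11	0.05	239	236
betB	betTABI	CPS_4011	CPS_1333	349	1112	17.09	0.11	0.01	1879	241
betI	betTABI	CPS_4012	CPS_1332	139	449	2.75	0.26	0.09	302	567
glyA	glyA-soxBDAG-purU	CPS_4031	CPS_2477	313	938	0.18	0.00	0.02	19	7
soxB	glyA-soxBDAG-purU	CPS_4032	CPS_2478	249	999	0.00	0.00	0.00	0	0
soxD	glyA-soxBDAG-purU	CPS_4033	CPS_2479	49	248	0.00	0.00	0.00	0	0
soxA	glyA-soxBDAG-purU	CPS_4034	CPS_2480	675	2346	0.00	0.00	0.00	0	0
soxG	glyA-soxBDAG-purU	CPS_4035	CPS_2481	213	381	0.01	0.00	0.00	1	0
purU	glyA-soxBDAG-purU	CPS_4036	CPS_2482	210	666	0.08	0.00	0.00	9	0.2
DNA binding protein	glyA-soxBDAG-purU	CPS_4037	CPS_2483	155	439	0.36	0.04	0.10	40	80
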