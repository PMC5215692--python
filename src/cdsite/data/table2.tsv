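snp_id	gene_label	raf_case	raf_control	p_value	odds_ratio	ci_low	ci_high	bonferroni_flag	composite_flag	note
rs7517847	IL23R	0.72	0.62	4.16E-07	0.6	0.5	0.8	1	0
rs11209026	IL23R	0.96	0.93	4.95E-03	0.6	0.4	0.9	0	0
rs2797685	PER3	0.23	0.19	7.30E-03	1.3	1.1	1.6	0	0
rs3024505	IL10	0.16	0.14	0.13576				0	0
rs10495903	THADA	0.13	0.10	2.39E-02	1.4	1.1	1.7	0	0
rs780093	GCKR	0.54	0.53	0.53107				0	0
rs2241880	ATG16L1	0.59	0.53	6.85E-03	1.3	1.1	1.5	0	0
rs9858542	BSN	0.38	0.30	6.17E-03	1.3	1.1	1.6	0	0
rs3197999	MST1	0.34	0.29	2.16E-02	1.2	1.2	1.5	0	0
rs2631367	SLC22A4	0.46	0.41	3.89E-02	1.2	1.0	1.4	0	0
rs1050152	SLC22A5	0.52	0.47	2.04E-02	1.2	1.0	1.4	0	0
rs11739135	IGR2198	0.44	0.40	3.56E-02	1.2	1.0	1.4	0	0
rs1521868	IGR2196	0.46	0.39	2.12E-03	1.3	1.1	1.5	1	0
rs1000113	IRGM	0.18	0.11	4.30E-06	1.7	1.4	2.2	1	0
rs4958847	IRGM	0.22	0.17	9.30E-04	1.4	1.2	1.8	1	0
rs9268832	MHC	0.77	0.73	0.17819				0	0
rs6930777	MHC	0.93	0.92	0.90981				0	0
rs9267798	MHC	0.07	0.07	0.95427				0	0
rs212388	TAGAP	0.42	0.41	0.52571				0	0
rs4263839	TNFSF15	0.76	0.68	1.00E-05	0.7	0.5	0.8	1	0
rs10761659	ZNF365	0.55	0.47	8.40E-04	1.3	1.1	1.6	1	0
rs150550	ZMIZ1	0.79	0.75	2.58E-02	0.8	0.7	1.0	0	0
rs11190140	NKX2/3	0.57	0.51	3.58E-03	0.8	0.7	0.9	0	0
rs2066844	NOD2	0.09	0.04	1.00E-05	2.1	1.5	3.0	1	0
rs2066845	NOD2	0.06	0.01	9.01E-08	3.8	2.3	6.9	1	0
rs2066847	NOD2	0.06	0.02	1.37E-06	2.9	1.8	4.6	1	0	ci_low from results text; table prints 2.9-4.6
rs2542151	PTPN2	0.16	0.12	8.41E-03	1.4	1.1	1.8	0	0
rs713875	MTMR3	0.54	0.48	5.43E-03	1.3	1.1	1.5	0	0
rs2413583	MAP3K7IP1	0.84	0.77	7.00E-05	0.7	0.5	0.8	1	0
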