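marker_id	gene_label	composite_flag	comparison	p_value	odds_ratio	ci_low	ci_high	bonferroni_flag
rs7517847	IL23R	0	L1_vs_ctrl	1.3E-03	0.4	0.2	0.7	1
rs7517847	IL23R	0	L2_vs_ctrl	4.8E-03	0.4	0.2	0.8	0
rs7517847	IL23R	0	L3_vs_ctrl	4.8E-03	0.5	0.3	0.8	0
rs11209026	IL23R	0	L3_vs_ctrl	3.1E-03	0.5	0.3	0.8	0
rs2797685	PER3	0	L1_vs_ctrl	2.1E-02	1.5	1.1	2.0	0
rs10495903	THADA	0	L1_vs_ctrl	2.5E-02	1.5	1.1	2.2	0
rs10495903	THADA	0	L3_vs_ctrl	3.8E-02	1.4	1.0	2.1	0
rs2241880	ATG16L1	0	L1_vs_ctrl	1.1E-02	1.7	1.1	2.6	0
rs2241880	ATG16L1	0	L3_vs_ctrl	1.3E-02	1.6	1.1	2.3	0
rs9858542	BSN	0	L1_vs_ctrl	2.6E-03	1.7	1.2	2.4	1
rs9858542	BSN	0	L2_vs_ctrl	2.2E-02	1.6	1.1	2.3	0
rs3197999	MST1	0	L1_vs_ctrl	1.9E-02	1.5	1.1	2.1	0
rs3197999	MST1	0	L2_vs_ctrl	7.5E-03	1.7	1.1	2.4	0
rs2631367	SLC22A4	0	L1_vs_ctrl	1.8E-02	1.6	1.1	2.4	0
rs1000113	IRGM	0	L1_vs_ctrl	6.0E-05	2.0	1.4	2.9	1
rs1000113	IRGM	0	L2_vs_ctrl	2.8E-02	1.6	1.1	2.3	0
rs1000113	IRGM	0	L3_vs_ctrl	2.3E-06	2.2	1.6	3.0	1
rs4958847	IRGM	0	L1_vs_ctrl	5.3E-03	1.6	1.1	2.2	0
rs4958847	IRGM	0	L3_vs_ctrl	9.8E-04	1.7	1.2	2.3	1
rs4263839	TNFSF15	0	L3_vs_ctrl	9.4E-04	0.3	0.2	0.7	1
rs4263839	TNFSF15	0	L3_vs_L2	3.9E-02	0.43	0.19	0.98	0
rs10761659	ZNF365	0	L2_vs_ctrl	5.5E-03	1.9	1.2	3.0	0
rs10761659	ZNF365	0	L3_vs_ctrl	1.4E-03	1.8	1.3	2.6	1
rs10761659	ZNF365	0	L3_vs_L1	4.7E-02	1.53	1.00	2.34	0
rs150550	ZMIZ1	0	L1_vs_ctrl	2.2E-02	2.9	1.1	7.5	0
rs11190140	NKX2/3	0	L2_vs_ctrl	1.1E-02	0.5	0.3	0.9	0
rs11190140	NKX2/3	0	L3_vs_ctrl	1.0E-02	0.6	0.4	0.9	0
rs11190140	NKX2/3	0	L1_vs_L2	2.6E-02	0.5	0.3	0.9	0
rs11190140	NKX2/3	0	L3_vs_L1	3.4E-02	0.61	0.39	0.97	0
rs2066844	NOD2	0	L1_vs_ctrl	1.4E-06	2.8	1.8	4.3	1
rs2066844	NOD2	0	L3_vs_ctrl	2.1E-03	1.9	1.3	3.0	1
rs2066844	NOD2	0	L1_vs_L2	2.4E-02	1.9	1.1	3.2	0
rs2066845	NOD2	0	L1_vs_ctrl	1.2E-05	3.8	2.0	7.1	1
rs2066845	NOD2	0	L2_vs_ctrl	2.7E-02	2.3	1.1	4.9	0
rs2066845	NOD2	0	L3_vs_ctrl	4.3E-09	4.9	2.8	8.9	1
rs2066845	NOD2	0	L3_vs_L2	2.2E-02	2.16	1.10	4.22	0
rs2066847	NOD2	0	L1_vs_ctrl	6.5E-07	3.7	2.1	6.4	1
rs2066847	NOD2	0	L3_vs_ctrl	3.7E-06	3.3	1.9	5.6	1
rs2066847	NOD2	0	L1_vs_L2	7.2E-05	5.7	2.2	15.0	1
rs2066847	NOD2	0	L3_vs_L2	2.2E-04	5.11	1.98	13.21	1
NOD2_any	NOD2	1	L1_vs_ctrl	9.6E-15	3.8	2.7	5.3	1
NOD2_any	NOD2	1	L3_vs_ctrl	5.0E-11	2.9	2.1	4.1	1
NOD2_any	NOD2	1	L1_vs_L2	6.2E-06	2.8	1.8	4.4	1
NOD2_any	NOD2	1	L3_vs_L2	4.2E-04	2.19	1.41	3.39	1
rs713875	MTMR3	0	L1_vs_ctrl	2.7E-03	1.8	1.2	2.7	0
rs713875	MTMR3	0	L3_vs_ctrl	3.1E-02	1.5	1.0	2.1	0
rs713875	MTMR3	0	L1_vs_L2	4.4E-02	1.7	1.0	2.8	0
rs2413583	MAP3K7IP1	0	L1_vs_ctrl	3.4E-03	0.2	0.04	0.6	0
rs2413583	MAP3K7IP1	0	L1_vs_L2	2.1E-02	0.2	0.04	0.9	0
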