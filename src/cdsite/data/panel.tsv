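snp_id	chrom_band	locus_id	gene_label	risk_allele	other_allele	allele_source
rs7517847	1p31.3	1p31.3	IL23R	T	G	convention
rs11209026	1p31.3	1p31.3	IL23R	G	A	convention
rs2797685	1p36.23	1p36.23	PER3	T	C	convention
rs3024505	1q32.1	1q32.1	IL10	A	G	convention
rs10495903	2p21	2p21	THADA	C	T	convention
rs780093	2p23.3	2p23.3	GCKR	T	C	convention
rs2241880	2q37.1	2q37.1	ATG16L1	G	A	convention
rs9858542	3p21.31	3p21.31	BSN	A	G	convention
rs3197999	3p21.31	3p21.31	MST1	A	G	convention
rs2631367	5q31	5q31	SLC22A4	C	G	convention
rs1050152	5q31	5q31	SLC22A5	T	C	convention
rs11739135	5q31	5q31	IGR2198	C	G	convention
rs1521868	5q31	5q31	IGR2196	T	G	convention
rs1000113	5q33.1	5q33.1	IRGM	T	C	convention
rs4958847	5q33.1	5q33.1	IRGM	A	G	convention
rs9268832	6p21	6p21	MHC	T	C	convention
rs6930777	6p21	6p21	MHC	A	G	convention
rs9267798	6p21	6p21	MHC	G	A	convention
rs212388	6q25.3	6q25.3	TAGAP	C	T	convention
rs4263839	9q32	9q32	TNFSF15	G	A	convention
rs10761659	10q21.2	10q21.2	ZNF365	A	G	convention
rs150550	10q22.3	10q22.3	ZMIZ1	T	G	convention
rs11190140	10q24.2	10q24.2	NKX2/3	T	C	convention
rs2066844	16q12.1	16q12.1	NOD2	T	C	convention
rs2066845	16q12.1	16q12.1	NOD2	C	G	convention
rs2066847	16q12.1	16q12.1	NOD2	C	G	convention
rs2542151	18p11.21	18p11.21	PTPN2	G	T	convention
rs713875	22q12.2	22q12.2	MTMR3	G	C	convention
rs2413583	22q13.1	22q13.1	MAP3K7IP1	C	T	convention
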