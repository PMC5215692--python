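covariate	category	group	n	pct
total	n	all	708
total	n	L1	237
total	n	L3	300
total	n	L2	171
gender	female	all	294	42
gender	female	L1	88	37
gender	female	L3	120	40
gender	female	L2	86	50
gender	male	all	414	58
gender	male	L1	149	63
gender	male	L3	180	60
gender	male	L2	85	50
age_decades	<=16	all	115	16
age_decades	<=16	L1	29	12
age_decades	<=16	L3	60	20
age_decades	<=16	L2	26	15
age_decades	17-40	all	442	63
age_decades	17-40	L1	150	63
age_decades	17-40	L3	186	62
age_decades	17-40	L2	106	62
age_decades	>40	all	151	21
age_decades	>40	L1	58	25
age_decades	>40	L3	54	18
age_decades	>40	L2	39	23
smoking	yes	all	218	31
smoking	yes	L1	76	32
smoking	yes	L3	95	32
smoking	yes	L2	47	27
smoking	no	all	366	53
smoking	no	L1	114	48
smoking	no	L3	156	52
smoking	no	L2	96	56
smoking	ex	all	108	16
smoking	ex	L1	38	16
smoking	ex	L3	43	14
smoking	ex	L2	27	16
smoking	missing	all	16
smoking	missing	L1	9
smoking	missing	L3	6
smoking	missing	L2	1
behavior	B1	all	537	76
behavior	B1	L1	164	69
behavior	B1	L3	224	75
behavior	B1	L2	149	87
behavior	B2	all	102	14
behavior	B2	L1	47	20
behavior	B2	L3	44	15
behavior	B2	L2	11	6
behavior	B3	all	69	10
behavior	B3	L1	26	11
behavior	B3	L3	32	10
behavior	B3	L2	11	6
familial_cd	yes	all	66	10
familial_cd	yes	L1	24	10
familial_cd	yes	L3	29	10
familial_cd	yes	L2	13	8
familial_cd	no	all	627	90
familial_cd	no	L1	208	90
familial_cd	no	L3	267	90
familial_cd	no	L2	152	92
familial_cd	missing	all	15
familial_cd	missing	L1	5
familial_cd	missing	L3	4
familial_cd	missing	L2	6
surgical_presentation	yes	all	88	13
surgical_presentation	yes	L1	41	18
surgical_presentation	yes	L3	37	13
surgical_presentation	yes	L2	10	6
surgical_presentation	no	all	574	87
surgical_presentation	no	L1	186	82
surgical_presentation	no	L3	238	87
surgical_presentation	no	L2	150	94
surgical_presentation	missing	all	46
surgical_presentation	missing	L1	10
surgical_presentation	missing	L3	25
surgical_presentation	missing	L2	11
perianal	yes	all	15	2
perianal	yes	L1	4	2
perianal	yes	L3	8	3
perianal	yes	L2	3	2
perianal	no	all	683	98
perianal	no	L1	229	98
perianal	no	L3	290	97
perianal	no	L2	164	98
perianal	missing	all	10
perianal	missing	L1	4
perianal	missing	L3	2
perianal	missing	L2	4
upper_gi	yes	all	47	7
upper_gi	yes	L1	17	7
upper_gi	yes	L3	25	8
upper_gi	yes	L2	5	3
upper_gi	no	all	661	93
upper_gi	no	L1	220	93
upper_gi	no	L3	275	92
upper_gi	no	L2	166	97
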