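mol_id	name	ob	dl	caco2	herbs
MOL000006	Luteolin	36.16	0.25	0.19	PHP,RMB
MOL000043	Atractylenolide I	37.37	0.15	1.30	AMK
MOL000098	Quercetin	46.43	0.28	0.05	HMM,HDW
MOL000211	Mairin	55.38	0.78	0.73	HMM
MOL000239	Jaranol	50.83	0.29	0.61	HMM
MOL000263	Oleanolic acid	29.02	0.76	0.59	RMB,HDW
MOL000296	Hederagenin	36.91	0.75	1.32	HMM,CZR
MOL000354	Isorhamnetin	49.60	0.31	0.31	HMM
MOL000358	Beta-sitosterol	36.91	0.75	1.32	PHP,HDW
MOL000409	Astragaloside IV	17.74	0.15	(2.22)	HMM
MOL000417	Calycosin	47.75	0.24	0.52	HMM
MOL000422	kaempferol	41.88	0.24	0.26	HMM
MOL000449	Stigmasterol	43.83	0.76	1.44	HDW
MOL000902	Curcumol	103.55	0.13	1.12	CZR
MOL000906	Wenjine	47.93	0.27	0.30	CZR
MOL001659	Poriferasterol	43.83	0.76	1.44	RMB,HDW
MOL001689	Acacetin	34.97	0.24	0.67	PHP
MOL006554	Taraxerol	38.40	0.77	1.37	PHP
MOL006756	Schottenol	37.42	0.75	1.33	PHP
MOL007111	Isotanshinone II	49.92	0.40	1.03	RMB
MOL007134	Danshensu	36.91	0.06	-0.27	RMB
MOL007151	Tanshindiol B	42.67	0.45	0.05	RMB
MOL007154	Tanshinone IIA	49.89	0.40	1.05	RMB
MOL007156	Tanshinone VI	45.64	0.30	0.48	RMB
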