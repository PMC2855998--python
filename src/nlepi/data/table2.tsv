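probe_id	symbol	fold_rm_hn	probability_score	t_p_value	fold_rm_pm	prior_study_flag
PS001	ATF3	5.72	1.52E-07	1.22E-06	3.39	1
PS002	FOS	4.62	1.23E-04	2.69E-05	2.81	1
PS003	FOSB	4.32	6.33E-04	7.99E-05	1.76	1
PS004	NR4A2	4.02	5.80E-07	4.57E-07	3.21	1
PS005	HIST1H2BG	3.99	5.15E-04	1.99E-01	4.40	0
PS006	CDH19	3.94	2.45E-04	1.73E-02	1.66	1
PS007	HIST1H2BB	3.85	7.53E-09	2.43E-08	4.21	1
PS008	NR4A2	3.83	2.76E-06	1.09E-05	3.43	1
PS009	IER2	3.77	1.08E-08	1.82E-08	3.52	1
PS010	BTG2	3.69	3.04E-07	2.15E-06	3.92	1
PS011	NA	3.68	1.37E-05	1.62E-05	4.57	1
PS012	NR4A2	3.46	6.02E-07	1.34E-06	3.33	1
PS013	EIF1	3.27	1.18E-07	5.47E-07	2.92	1
PS014	JUN	3.26	1.32E-08	6.70E-09	1.87	1
PS015	ZFAND5	3.10	2.37E-05	1.21E-03	4.03	0
PS016	NA	2.92	3.15E-05	2.44E-04	2.13	1
PS017	DUSP1	2.87	1.07E-05	4.37E-06	2.17	1
PS018	NR4A3	2.85	3.72E-06	3.48E-05	3.07	1
PS019	CD69	2.84	1.38E-04	8.07E-04	4.85	1
PS020	SPRY1	2.70	3.26E-04	2.37E-03	3.19	0
PS021	IL6	2.66	5.84E-04	7.09E-03	2.56	0
PS022	PTP4A1	2.65	2.12E-07	1.01E-06	2.69	1
PS023	TRIM37	2.60	3.61E-04	3.88E-03	3.63	0
PS024	RGS2	2.60	1.24E-03	1.28E-03	1.37	1
PS025	KLF4	2.59	2.54E-04	6.69E-04	1.56	1
PS026	CX3CR1	2.58	1.69E-04	2.14E-02	2.65	0
PS027	NR4A1	2.56	4.63E-04	7.42E-04	1.98	1
PS028	H3F3B	2.53	1.04E-07	7.24E-08	1.93	1
PS029	DUSP2	2.53	4.35E-04	4.81E-03	1.25	1
PS030	TXNIP	2.50	3.17E-04	5.90E-04	2.96	0
PS031	PTGS2	2.47	7.16E-04	3.11E-03	1.87	1
PS032	EGR1	2.47	3.83E-04	2.34E-04	3.64	1
PS033	SNF1LK	2.37	2.84E-05	4.52E-05	2.55	1
PS034	EGR1	2.37	7.45E-05	4.98E-05	2.63	1
PS035	PTP4A1	2.34	2.92E-05	7.13E-04	2.62	1
PS036	CD93	2.33	2.54E-04	4.60E-03	2.58	0
PS037	MAFF	2.31	5.29E-04	1.04E-03	2.86	0
PS038	SAV1	2.29	6.26E-04	1.00E-02	2.94	0
PS039	EIF4A1	2.28	2.92E-06	9.00E-06	2.38	1
PS040	JUN	2.25	3.43E-08	7.17E-08	3.39	1
PS041	ZFP36	2.23	1.29E-04	4.28E-04	2.04	1
PS042	RGS5	2.23	1.34E-03	1.97E-03	2.49	0
PS043	YWHAZ	2.22	5.60E-04	4.32E-03	1.93	1
PS044	PNMAL1	2.20	1.05E-03	1.18E-02	1.88	0
PS045	JUN	2.19	2.34E-05	1.20E-05	2.13	1
PS046	MCL1	2.17	5.52E-05	3.24E-04	2.47	1
PS047	FRZB	2.15	1.36E-03	2.02E-02	2.44	0
PS048	ITGBL1	2.15	1.67E-03	2.23E-02	1.85	0
PS049	ABLIM1	2.13	7.96E-05	1.29E-04	2.07	0
PS050	NEDD4L	2.11	8.35E-05	1.15E-04	2.13	0
PS051	ARL4C	2.11	4.00E-05	3.43E-04	1.83	0
PS052	AQP3	2.11	1.46E-03	1.01E-02	2.15	0
PS053	AHNAK	2.11	2.59E-04	1.54E-03	1.74	0
PS054	LEPROT	2.10	1.05E-03	1.93E-03	3.10	0
PS055	MCL1	2.10	2.20E-04	6.17E-04	1.98	0
PS056	CHN1	2.10	9.45E-04	5.86E-03	1.67	0
PS057	SEMA5A	2.10	6.21E-04	4.38E-03	1.86	0
PS058	RGS5	2.10	1.02E-03	3.52E-03	2.75	0
PS059	IER3	2.09	3.00E-04	6.81E-04	1.76	0
PS060	TIMM23	2.08	8.16E-06	1.41E-05	2.29	0
PS061	NSF	2.08	5.52E-04	7.69E-03	2.50	0
PS062	PTP4A1	2.08	6.24E-04	3.98E-03	1.81	1
PS063	FHL1	2.08	1.50E-03	3.17E-02	1.46	0
PS064	BAG5	2.08	6.01E-04	6.49E-03	2.29	0
PS065	EIF5	2.05	5.40E-05	4.01E-04	1.97	1
PS066	NIPBL	2.04	1.01E-04	3.74E-04	1.74	0
PS067	GMPPA	0.48	6.45E-04	8.71E-03	0.58	0
PS068	TRO	0.48	1.27E-03	8.30E-04	0.37	1
PS069	GNB2	0.48	2.13E-04	1.04E-03	0.49	0
PS070	CST3	0.47	1.49E-03	7.13E-03	0.41	0
PS071	PDXDC2	0.47	8.07E-04	2.90E-03	0.35	0
PS072	ZYX	0.47	3.92E-04	7.60E-04	0.38	0
PS073	UBA1	0.47	1.32E-03	3.54E-03	0.41	0
PS074	MARCKS	0.47	1.41E-03	2.02E-02	0.35	0
PS075	RARA	0.46	3.51E-04	5.48E-04	0.47	0
PS076	PELP1	0.46	2.85E-05	8.64E-05	0.48	0
PS077	PRDX2	0.46	1.32E-03	6.95E-04	0.41	0
PS078	RPL28	0.45	1.35E-04	1.47E-04	0.42	0
PS079	COL16A1	0.44	1.41E-03	9.05E-04	0.40	0
PS080	BAT2	0.44	4.61E-04	1.46E-02	0.45	0
PS081	PLTP	0.44	5.35E-04	1.65E-03	0.39	0
PS082	CLU	0.44	2.13E-04	5.33E-04	0.52	0
PS083	PIB5PA	0.43	3.66E-04	1.21E-04	0.35	0
PS084	TNC	0.42	4.90E-04	6.46E-03	0.56	0
PS085	IFI6	0.42	2.74E-04	5.88E-03	0.65	0
PS086	INTS3	0.42	6.59E-04	9.70E-04	0.46	0
PS087	H2AFX	0.42	2.56E-04	4.63E-04	0.41	0
PS088	FLJ11292	0.42	9.81E-04	1.83E-01	0.71	0
PS089	RPS26	0.42	9.31E-04	1.40E-03	0.36	0
PS090	IFI35	0.40	7.07E-04	4.10E-04	0.43	0
PS091	ZFP36L2	0.40	1.38E-03	5.99E-02	0.45	0
PS092	C17orf101	0.38	3.20E-04	4.73E-04	0.39	0
PS093	LRRC14	0.37	1.08E-03	9.10E-04	0.32	0
PS094	NPIPL3	0.34	1.10E-03	3.59E-03	0.78	0
PS095	BST2	0.31	9.68E-05	9.65E-03	0.33	0
PS096	SEC14L1	0.30	4.14E-05	6.00E-03	0.42	0
PS097	CALD1	0.27	7.01E-06	5.90E-05	0.21	0
PS098	CSN2	0.10	9.09E-05	1.52E-01	1.30	0
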