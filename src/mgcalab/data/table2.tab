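# Station/chamber-mean Mg/Ca fixture: G. ruber chamber means (mmol/mol, ±1 sigma)
# per plankton-tow sample with sea-surface (SST), mixed-layer (T_MLD) and
# in-situ temperatures (degC). Chambers: F0 final, F-1 penultimate,
# F-2 antepenultimate. Device: MN multinet, BN bongonet. Missing values:
# n.a. (not available), n.app. (not applicable).
sample_number	device	water_depth_m	mgca_f0	sigma_f0	mgca_f1	sigma_f1	mgca_f2	sigma_f2	sst_c	t_mld_c	t_insitu_c
ES19C08_008_01	MN	20-40	1.48	0.10	2.69	0.23	2.08	0.24	19.75	19.70	19.64
ES19C08_008_01	MN	40-60	2.43	0.21	3.55	0.19	3.20	0.15	19.75	19.70	19.50
ES19C08_008_01	MN	20-100	2.13	0.18	3.23	0.25	3.01	0.24	19.75	19.70	19.50
ES19C08_008_02	MN	150-500	2.83	0.23	3.66	0.25	3.51	0.27	19.66	19.66	n.app.
ES19C12_012_03	BN	50	2.53	0.28	3.89	0.25	4.58	0.40	21.91	21.62	21.20
ES19C12_012_06	BN	50	3.88	0.22	3.86	0.38	4.71	0.44	22.31	21.84	21.08
ES19C12_012_05	MN	60-100	n.a.	n.a.	3.87	0.24	4.70	0.36	22.44	22.03	n.a.
ES19C12_012_10	MN	0-20	5.00	0.63	5.11	0.21	3.72	0.25	22.04	21.59	22.38
ES19C12_012_10	MN	60-100	2.45	0.25	4.31	0.24	3.74	0.26	22.04	21.59	n.a.
ES19C14_015_03	BN	40	2.08	0.24	3.84	0.20	4.08	0.30	20.45	19.37	17.32
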