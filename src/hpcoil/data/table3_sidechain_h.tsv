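residue	atom	nucleus	variant	delta0	b1	err_b1	b2	err_b2	ratio	err_ratio	bracketed	stereo_status	printed_row	source
Arg	HG2	1H	.	1.633	-0.104	0.009	0.06	0.04	-0.58	0.39	n	degenerate	1	tab3
Arg	HG3	1H	.	1.633	-0.104	0.009	0.06	0.04	-0.58	0.39	n	degenerate	2	tab3
Arg	HD2	1H	.	3.204	-0.088	0.007	0.04	0.03	-0.45	0.34	n	degenerate	3	tab3
Arg	HD3	1H	.	3.204	-0.088	0.007	0.04	0.03	-0.45	0.34	n	degenerate	4	tab3
Gln	HG2	1H	.	2.371	-0.037	0.010	-0.01	0.05	0.27	1.35	y	degenerate	5	tab3
Gln	HG3	1H	.	2.371	-0.037	0.010	-0.01	0.05	0.27	1.35	y	degenerate	6	tab3
Glu	HG2	1H	.	2.324	-0.078	0.014	-0.11	0.07	1.41	0.93	n	degenerate	7	tab3
Glu	HG3	1H	.	2.324	-0.078	0.014	-0.11	0.07	1.41	0.93	n	degenerate	8	tab3
His	HD2	1H	pH:4.0	7.284	0.013	0.005	0.01	0.02	0.77	1.57	y	stereospecific	9	tab3
His	HE1	1H	pH:4.0	8.598	0.064	0.003	-0.03	0.01	-0.47	0.16	n	stereospecific	10	tab3
His	HD2	1H	pH:8.5	6.971	0.094	0.057	-0.23	0.28	-2.45	3.33	y	stereospecific	11	tab3
His	HE1	1H	pH:8.5	7.702	0.137	0.061	0.07	0.30	0.51	2.20	n	stereospecific	12	tab3
Ile	HG12	1H	.	1.188	-0.117	0.020	0.18	0.10	-1.54	0.89	n	tentative	13	tab3
Ile	HG13	1H	.	1.452	-0.143	0.018	-0.12	0.09	0.84	0.64	n	tentative	14	tab3
Ile	QG2	1H	.	0.924	-0.087	0.005	0.04	0.03	-0.46	0.35	n	stereospecific	15	tab3
Ile	QD1	1H	.	0.866	-0.099	0.006	0.07	0.03	-0.71	0.31	n	stereospecific	16	tab3
Leu	HG	1H	.	1.634	-0.125	0.002	-0.005	0.008	0.04	0.06	y	stereospecific	17	tab3
Leu	QD1	1H	.	0.928	-0.070	0.001	0.030	0.005	-0.43	0.07	n	stereospecific	18	tab3
Leu	QD2	1H	.	0.874	-0.064	0.002	0.01	0.01	-0.16	0.16	y	stereospecific	19	tab3
Lys	HG2	1H	.	1.433	-0.159	0.012	0.15	0.06	-0.94	0.38	n	degenerate	20	tab3
Lys	HG3	1H	.	1.433	-0.159	0.012	0.15	0.06	-0.94	0.38	n	degenerate	21	tab3
Lys	HD2	1H	.	1.678	-0.108	0.007	0.06	0.03	-0.56	0.28	n	degenerate	22	tab3
Lys	HD3	1H	.	1.678	-0.108	0.007	0.06	0.03	-0.56	0.28	n	degenerate	23	tab3
Lys	HE2	1H	.	2.989	-0.071	0.003	0.03	0.01	-0.42	0.14	n	degenerate	24	tab3
Lys	HE3	1H	.	2.989	-0.071	0.003	0.03	0.01	-0.42	0.14	n	degenerate	25	tab3
Met	HG2	1H	.	2.542	-0.109	0.004	0.05	0.02	-0.46	0.18	n	ambiguous	26	tab3
Met	HG3	1H	.	2.614	-0.131	0.002	0.13	0.01	-0.99	0.08	n	ambiguous	27	tab3
Met	QE	1H	.	2.098	-0.070	0.003	0.04	0.01	-0.57	0.14	n	stereospecific	28	tab3
Phe	HD1	1H	.	7.277	-0.065	0.007	0.15	0.03	-2.31	0.52	n	degenerate	29	tab3
Phe	HD2	1H	.	7.277	-0.065	0.007	0.15	0.03	-2.31	0.52	n	degenerate	29	tab3
Phe	HE1	1H	.	7.375	-0.019	0.008	0.12	0.04	-6.32	3.39	n	degenerate	30	tab3
Phe	HE2	1H	.	7.375	-0.019	0.008	0.12	0.04	-6.32	3.39	n	degenerate	30	tab3
Phe	HZ	1H	.	7.346	-0.008	0.009	0.10	0.04	-12.5	14.9	y	stereospecific	31	tab3
Pro	HG2	1H	pro:cis	1.848	-0.162	0.010	0.24	0.05	-1.48	0.32	n	ambiguous	32	tab3
Pro	HG3	1H	pro:cis	1.943	-0.076	0.010	0.15	0.05	-1.97	0.71	n	ambiguous	33	tab3
Pro	HD2	1H	pro:cis	3.530	-0.121	0.005	0.12	0.02	-0.99	0.17	n	ambiguous	34	tab3
Pro	HD3	1H	pro:cis	3.575	-0.079	0.005	0.11	0.02	-1.39	0.27	n	ambiguous	35	tab3
Pro	HG2	1H	pro:trans	2.021	-0.110	0.005	0.12	0.02	-1.09	0.19	n	degenerate	36	tab3
Pro	HG3	1H	pro:trans	2.021	-0.110	0.005	0.12	0.02	-1.09	0.19	n	degenerate	37	tab3
Pro	HD2	1H	pro:trans	3.638	-0.089	0.020	-0.05	0.10	0.56	1.13	y	degenerate	38	tab3
Pro	HD3	1H	pro:trans	3.638	-0.089	0.020	-0.05	0.10	0.56	1.13	y	degenerate	39	tab3
Thr	QG2	1H	.	1.212	-0.049	0.002	0.02	0.01	-0.41	0.20	n	stereospecific	40	tab3
Trp	HD1	1H	.	7.264	0.015	0.009	0.19	0.05	12.67	8.30	n	stereospecific	41	tab3
Trp	HE3	1H	.	7.642	-0.113	0.010	0.08	0.05	-0.71	0.45	n	stereospecific	42	tab3
Trp	HZ2	1H	.	7.498	0.003	0.006	0.08	0.03	26.7	54.3	y	stereospecific	43	tab3
Trp	HZ3	1H	.	7.171	-0.047	0.014	0.12	0.07	-2.55	1.67	n	stereospecific	44	tab3
Trp	HH2	1H	.	7.247	-0.030	0.018	0.14	0.09	-4.67	4.10	n	stereospecific	45	tab3
Tyr	HD1	1H	.	7.139	-0.058	0.007	0.09	0.03	-1.55	0.55	n	degenerate	46	tab3
Tyr	HD2	1H	.	7.139	-0.058	0.007	0.09	0.03	-1.55	0.55	n	degenerate	46	tab3
Tyr	HE1	1H	.	6.848	-0.023	0.005	0.10	0.03	-4.35	1.61	n	degenerate	47	tab3
Tyr	HE2	1H	.	6.848	-0.023	0.005	0.10	0.03	-4.35	1.61	n	degenerate	47	tab3
Val	QG1	1H	.	0.945	-0.067	0.002	0.04	0.01	-0.60	0.15	n	stereospecific	48	tab3
Val	QG2	1H	.	0.931	-0.068	0.003	0.04	0.01	-0.59	0.15	n	stereospecific	49	tab3
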