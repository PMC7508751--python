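residue	atom	nucleus	variant	delta0	b1	err_b1	b2	err_b2	ratio	err_ratio	bracketed	stereo_status	source
Ala	QB	1H	.	1.392	-0.022	0.001	0.02	0.01	-0.91	0.46	n	stereospecific	tab2
Arg	HB2	1H	.	1.769	-0.026	0.005	0.00	0.02	0.00	.	n	ambiguous	tab2
Arg	HB3	1H	.	1.874	-0.077	0.005	0.03	0.02	-0.39	0.26	n	ambiguous	tab2
Asn	HB2	1H	.	2.839	0.042	0.011	-0.13	0.06	-3.10	1.64	n	stereospecific	tab2
Asn	HB3	1H	.	2.746	0.072	0.014	-0.12	0.07	-1.67	1.03	n	stereospecific	tab2
Asp	HB2	1H	.	2.623	0.083	0.008	-0.06	0.04	-0.72	0.49	n	tentative	tab2
Asp	HB3	1H	.	2.704	0.073	0.007	-0.05	0.03	-0.68	0.42	n	tentative	tab2
Cys	HB2	1H	cys:red	2.938	-0.001	0.001	-0.01	0.01	10.0	14.1	y	degenerate	tab2
Cys	HB3	1H	cys:red	2.938	-0.001	0.001	-0.01	0.01	10.0	14.1	y	degenerate	tab2
Cys	HB2	1H	cys:ox	2.982	0.053	0.007	-0.03	0.03	-0.49	0.55	y	ambiguous	tab2
Cys	HB3	1H	cys:ox	3.256	-0.050	0.001	0.03	0.01	-0.52	0.14	n	ambiguous	tab2
Gln	HB2	1H	.	2.133	-0.099	0.013	0.09	0.06	-0.91	0.62	n	stereospecific	tab2
Gln	HB3	1H	.	1.987	-0.041	0.010	0.05	0.05	-1.22	1.26	y	stereospecific	tab2
Glu	HB2	1H	.	1.948	0.018	0.010	-0.11	0.05	-6.11	4.39	n	tentative	tab2
Glu	HB3	1H	.	2.095	-0.190	0.035	0.24	0.17	-1.26	0.92	n	tentative	tab2
His	HB2	1H	pH:4.0	3.163	0.020	0.003	-0.01	0.01	-0.5	0.5	y	tentative	tab2
His	HB3	1H	pH:4.0	3.284	-0.085	0.010	0.18	0.05	-2.12	0.64	n	tentative	tab2
His	HB2	1H	pH:8.5	3.036	0.027	0.012	-0.02	0.06	-0.74	2.25	y	tentative	tab2
His	HB3	1H	pH:8.5	3.101	-0.059	0.008	0.10	0.04	-1.69	0.72	n	tentative	tab2
Ile	HB	1H	.	1.881	-0.018	0.006	0.04	0.03	-2.22	1.82	n	stereospecific	tab2
Leu	HB2	1H	.	1.584	-0.028	0.001	0.04	0.01	-1.43	0.36	n	tentative	tab2
Leu	HB3	1H	.	1.652	-0.048	0.001	0.04	0.01	-0.83	0.21	n	tentative	tab2
Lys	HB2	1H	.	1.758	-0.041	0.002	0.02	0.01	-0.49	0.29	n	ambiguous	tab2
Lys	HB3	1H	.	1.846	-0.103	0.007	0.07	0.03	-0.68	0.39	n	ambiguous	tab2
Met	HB2	1H	.	2.004	-0.026	0.003	0.02	0.01	-0.77	0.40	n	tentative	tab2
Met	HB3	1H	.	2.114	-0.087	0.005	0.10	0.02	-1.15	0.24	n	tentative	tab2
Phe	HB2	1H	.	3.049	0.013	0.010	-0.02	0.05	-1.54	4.02	y	tentative	tab2
Phe	HB3	1H	.	3.129	-0.049	0.007	0.14	0.03	-2.86	0.74	n	tentative	tab2
Pro	HB2	1H	pro:cis	2.189	-0.083	0.013	0.10	0.06	-1.20	0.75	n	tentative	tab2
Pro	HB3	1H	pro:cis	2.359	-0.076	0.009	0.08	0.04	-1.05	0.54	n	tentative	tab2
Pro	HB2	1H	pro:trans	2.033	-0.078	0.009	0.13	0.04	-1.67	0.55	n	tentative	tab2
Pro	HB3	1H	pro:trans	2.205	-0.070	0.010	0.10	0.05	-1.43	0.74	n	tentative	tab2
Ser	HB2	1H	.	3.881	-0.015	0.005	-0.01	0.03	0.67	2.01	y	ambiguous	tab2
Ser	HB3	1H	.	3.881	-0.015	0.005	0.03	0.03	-2.00	2.11	y	ambiguous	tab2
Thr	HB	1H	.	4.255	0.001	0.003	0.06	0.01	60	180	y	stereospecific	tab2
Trp	HB2	1H	.	3.277	-0.024	0.008	0.02	0.04	-0.83	1.69	y	degenerate	tab2
Trp	HB3	1H	.	3.277	-0.024	0.008	0.02	0.04	-0.83	1.69	y	degenerate	tab2
Tyr	HB2	1H	.	2.972	0.037	0.010	-0.13	0.05	-3.51	1.65	n	tentative	tab2
Tyr	HB3	1H	.	3.037	-0.090	0.019	0.34	0.09	-3.78	1.28	n	tentative	tab2
Val	HB	1H	.	2.093	0.007	0.004	-0.09	0.02	-12.86	7.88	n	stereospecific	tab2
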