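residue	atom	nucleus	variant	delta0	b1	err_b1	b2	err_b2	ratio	err_ratio	bracketed	stereo_status	source
Arg	NE	15N	.	84.34	1.8	0.3	-4	2	-2.22	1.17	n	stereospecific	tab4
Arg	HE	1H	.	7.245	-0.14	0.01	-0.13	0.07	0.93	0.50	n	stereospecific	tab4
Arg	NH1	15N	.	70.48	5.4	0.2	-6.0	0.9	-1.11	0.17	n	stereospecific	tab4
Arg	QH1	1H	.	6.490	0.025	0.001	-0.02	0.01	-0.80	0.40	n	stereospecific	tab4
Arg	NH2	15N	.	71.78	5.6	0.2	-8.8	0.9	-1.57	0.17	n	stereospecific	tab4
Arg	QH2	1H	.	6.892	-0.026	0.006	-0.14	0.04	5.38	1.98	n	stereospecific	tab4
Asn	ND2	15N	.	113.25	7.7	0.2	-3.2	0.9	-0.42	0.12	n	stereospecific	tab4
Asn	HD21	1H	.	7.691	0.14	0.01	0.25	0.05	1.79	0.38	n	stereospecific	tab4
Asn	HD22	1H	.	6.990	0.39	0.01	-0.07	0.05	-0.18	0.13	n	stereospecific	tab4
Gln	NE2	15N	.	112.93	7.5	0.1	-5.7	0.7	-0.76	0.09	n	stereospecific	tab4
Gln	HE21	1H	.	7.639	0.09	0.01	0.16	0.05	1.78	0.59	n	stereospecific	tab4
Gln	HE22	1H	.	6.939	0.41	0.01	-0.28	0.05	-0.68	0.12	n	stereospecific	tab4
His	ND1	15N	pH:4.0	175.84	0.216	0.005	-0.19	0.02	-0.88	0.09	n	stereospecific	tab4
His	NE2	15N	pH:4.0	173.14	2.08	0.06	-4.7	0.3	-2.26	0.16	n	stereospecific	tab4
Lys	NZ	15N	.	32.61	3.0	0.3	-2.0	1.5	-0.67	0.51	n	stereospecific	tab4
Lys	QZ	1H	.	7.57	-0.44	0.03	0.2	0.2	-0.45	0.46	n	stereospecific	tab4
Trp	NE1	15N	.	129.51	2.84	0.08	-1.4	0.3	-0.49	0.11	n	stereospecific	tab4
Trp	HE1	1H	.	10.197	-0.24	0.01	0.63	0.05	-2.63	0.24	n	stereospecific	tab4
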