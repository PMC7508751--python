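residue	atom	variant	delta_sail	sail_weak	delta_unlabeled	diff
Arg	HB2	.	1.862	y	1.898	0.036
Arg	HB3	.	1.881	n	1.898	0.017
Arg	HG2	.	.	.	1.708	.
Arg	HG3	.	1.594	n	1.629	0.035
Arg	HD2/HD3	.	3.205	n	3.233	0.028
Asn	HB2	.	2.820	n	2.842	0.022
Asn	HB3	.	2.918	y	2.939	0.021
Asp	HB2	.	2.641	n	2.661	0.020
Asp	HB3	.	.	.	2.805	.
Cys	HB2	cys:red	3.070	n	3.090	0.020
Cys	HB3	cys:red	.	.	3.010	.
Cys	HB2	cys:ox	3.137	n	3.160	0.023
Cys	HB3	cys:ox	.	.	3.374	.
Gln	HB2/HB3	.	2.095	n	2.122	0.027
Gln	HG2/HG3	.	2.422	n	2.437	0.015
Glu	HB2	.	2.020	n	2.050	0.030
Glu	HB3	.	2.103	y	2.118	0.015
Glu	HG2/HG3	.	2.323	n	2.339	0.016
His	HB2	.	3.103	n	3.129	0.026
His	HB3	.	.	.	3.226	.
Ile	HG12	.	1.206	n	1.247	0.041
Ile	HG13	.	1.414	y	1.451	0.037
Leu	HB2	.	.	.	1.677	.
Leu	HB3	.	1.693	n	1.713	0.020
Leu	HG	.	1.652	n	1.691	0.039
Lys	HB2/HB3	.	1.864	n	1.889	0.025
Lys	HG2	.	1.459	y	1.489	0.030
Lys	HG3	.	1.376	n	1.419	0.043
Lys	HD2/HD3	.	1.674	n	1.709	0.035
Lys	HE2/HE3	.	2.984	n	3.009	0.025
Met	HB2	.	2.085	n	2.117	0.032
Met	HB3	.	2.160	y	2.182	0.022
Met	HG2/HG3	.	2.592	n	2.623	0.031
Phe	HB2	.	.	.	3.110	.
Phe	HB3	.	3.255	n	3.272	0.017
Pro	HB2	.	2.028	n	2.054	0.026
Pro	HB3	.	2.325	y	2.339	0.014
Pro	HG2/HG3	.	1.950	n	1.996	0.046
Pro	HD2	.	3.386	n	3.406	0.020
Pro	HD3	.	3.301	y	3.320	0.019
Ser	HB2	.	3.916	y	3.935	0.019
Ser	HB3	.	3.948	n	3.971	0.023
Trp	HB2	.	.	.	3.293	.
Trp	HB3	.	3.454	n	3.473	0.019
Tyr	HB2	.	3.026	y	3.040	0.014
Tyr	HB3	.	3.166	n	3.185	0.019
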