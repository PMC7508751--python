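neighbor	variant	atom	offset	c1	c2
Ala	.	HN	-1	0.07	-0.11
Ala	.	HN	+1	0.08	-0.19
Ala	.	HN	+2	0.02	0.02
Ala	.	HA	-1	-0.02	0.05
Ala	.	HA	+1	-0.01	-0.02
Ala	.	HA	+2	0.01	0.01
Ala	.	HB_ALA	-1	0.00	-0.01
Arg	.	HN	-1	0.01	0.12
Arg	.	HN	+1	0.04	0.04
Arg	.	HN	+2	0.00	0.01
Arg	.	HA	-1	-0.03	0.02
Arg	.	HA	+1	-0.05	0.10
Arg	.	HA	+2	-0.01	0.05
Arg	.	HB_ALA	-1	-0.01	0.02
Asn	.	HN	-1	0.05	-0.02
Asn	.	HN	+1	0.01	-0.09
Asn	.	HN	+2	-0.01	0.02
Asn	.	HA	-1	0.01	-0.08
Asn	.	HA	+1	-0.02	0.01
Asn	.	HA	+2	-0.02	0.12
Asn	.	HB_ALA	-1	-0.02	0.03
Asp	.	HN	-1	0.06	-0.19
Asp	.	HN	+1	0.21	0.34
Asp	.	HN	+2	0.03	0.01
Asp	.	HA	-1	0.01	0.00
Asp	.	HA	+1	-0.05	0.12
Asp	.	HA	+2	-0.03	0.06
Asp	.	HB_ALA	-1	-0.01	0.01
Cys	.	HN	-1	0.02	-0.12
Cys	.	HN	+1	-0.08	0.00
Cys	.	HN	+2	0.11	-0.02
Cys	.	HA	-1	0.01	-0.09
Cys	.	HA	+1	-0.01	-0.01
Cys	.	HA	+2	-0.01	-0.01
Cys	.	HB_ALA	-1	0.00	-0.01
Gln	.	HN	-1	-0.04	0.32
Gln	.	HN	+1	-0.02	0.17
Gln	.	HN	+2	0.01	-0.02
Gln	.	HA	-1	-0.05	0.08
Gln	.	HA	+1	-0.02	-0.02
Gln	.	HA	+2	0.00	0.01
Gln	.	HB_ALA	-1	0.00	-0.01
Glu	.	HN	-1	0.11	-0.27
Glu	.	HN	+1	0.04	-0.08
Glu	.	HN	+2	0.15	-0.15
Glu	.	HA	-1	-0.03	0.02
Glu	.	HA	+1	-0.02	-0.01
Glu	.	HA	+2	-0.01	0.01
Glu	.	HB_ALA	-1	-0.01	0.00
Gly	.	HN	-1	0	0
Gly	.	HN	+1	0	0
Gly	.	HN	+2	0	0
Gly	.	HA	-1	0	0
Gly	.	HA	+1	0	0
Gly	.	HA	+2	0	0
Gly	.	HB_ALA	-1	0	0
His	pH:4.0	HN	-1	0.00	-0.12
His	pH:4.0	HN	+1	0.04	-0.08
His	pH:4.0	HN	+2	0.01	-0.03
His	pH:4.0	HA	-1	-0.03	0.03
His	pH:4.0	HA	+1	0.00	-0.04
His	pH:4.0	HA	+2	-0.01	0.00
His	pH:4.0	HB_ALA	-1	-0.02	0.01
Ile	.	HN	-1	0.14	-0.07
Ile	.	HN	+1	-0.04	-0.09
Ile	.	HN	+2	0.05	-0.36
Ile	.	HA	-1	-0.04	0.01
Ile	.	HA	+1	-0.04	0.13
Ile	.	HA	+2	0.00	0.02
Ile	.	HB_ALA	-1	0.01	-0.03
Leu	.	HN	-1	0.18	-0.13
Leu	.	HN	+1	0.10	-0.15
Leu	.	HN	+2	0.03	-0.05
Leu	.	HA	-1	-0.03	0.02
Leu	.	HA	+1	-0.02	0.00
Leu	.	HA	+2	0.01	-0.02
Leu	.	HB_ALA	-1	-0.01	0.02
Lys	.	HN	-1	0.12	-0.03
Lys	.	HN	+1	0.09	-0.36
Lys	.	HN	+2	0.05	-0.18
Lys	.	HA	-1	-0.02	0.07
Lys	.	HA	+1	0.02	-0.07
Lys	.	HA	+2	0.01	0.00
Lys	.	HB_ALA	-1	0.00	-0.01
Met	.	HN	-1	0.14	-0.17
Met	.	HN	+1	0.07	-0.13
Met	.	HN	+2	0.01	0.01
Met	.	HA	-1	-0.03	0.06
Met	.	HA	+1	0.00	0.03
Met	.	HA	+2	0.00	0.01
Met	.	HB_ALA	-1	0.00	-0.01
Phe	.	HN	-1	0.10	0.01
Phe	.	HN	+1	-0.09	-0.25
Phe	.	HN	+2	0.02	0.07
Phe	.	HA	-1	-0.04	0.14
Phe	.	HA	+1	-0.02	-0.01
Phe	.	HA	+2	-0.02	-0.01
Phe	.	HB_ALA	-1	-0.01	0.03
Pro	pro:trans	HN	-1	0.13	-0.21
Pro	pro:trans	HN	+1	-0.06	-0.06
Pro	pro:trans	HN	+2	0.25	-0.41
Pro	pro:trans	HA	-1	-0.03	0.06
Pro	pro:trans	HA	+1	-0.01	-0.01
Pro	pro:trans	HA	+2	0.00	-0.01
Pro	pro:trans	HB_ALA	-1	0.01	-0.02
Ser	.	HN	-1	-0.02	-0.03
Ser	.	HN	+1	0.02	-0.11
Ser	.	HN	+2	0.04	-0.22
Ser	.	HA	-1	-0.01	0.03
Ser	.	HA	+1	0.00	0.00
Ser	.	HA	+2	0.00	-0.01
Ser	.	HB_ALA	-1	-0.01	-0.01
Thr	.	HN	-1	0.09	-0.24
Thr	.	HN	+1	-0.02	0.11
Thr	.	HN	+2	0.00	-0.03
Thr	.	HA	-1	-0.03	0.02
Thr	.	HA	+1	-0.01	-0.03
Thr	.	HA	+2	0.00	0.00
Thr	.	HB_ALA	-1	0.00	0.00
Trp	.	HN	-1	0.16	-0.25
Trp	.	HN	+1	0.03	-0.07
Trp	.	HN	+2	0.09	-0.08
Trp	.	HA	-1	-0.14	0.06
Trp	.	HA	+1	-0.03	-0.03
Trp	.	HA	+2	0.04	-0.09
Trp	.	HB_ALA	-1	-0.12	-0.05
Tyr	.	HN	-1	0.16	-0.24
Tyr	.	HN	+1	-0.13	-0.21
Tyr	.	HN	+2	-0.02	0.26
Tyr	.	HA	-1	-0.04	0.07
Tyr	.	HA	+1	-0.03	0.01
Tyr	.	HA	+2	-0.01	0.04
Tyr	.	HB_ALA	-1	-0.01	0.03
Val	.	HN	-1	0.08	0.05
Val	.	HN	+1	-0.13	0.21
Val	.	HN	+2	-0.02	0.13
Val	.	HA	-1	-0.05	0.05
Val	.	HA	+1	-0.01	-0.03
Val	.	HA	+2	-0.01	0.04
Val	.	HB_ALA	-1	0.01	0.00
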