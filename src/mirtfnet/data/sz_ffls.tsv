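no	gene	mirna	matrices	consensus	tf_symbols
1	ARVCF	hsa-miR-29b-2	V$TCF11MAFG_01	ATGACTCAGCANTTNNG	NFE2L1,MAFG
2	ARVCF	hsa-miR-29c	V$TCF11MAFG_01	ATGACTCAGCANTTNNG	NFE2L1,MAFG
3	BDNF	hsa-miR-195	V$NFKB_C	GGGACTTTCCA	NFKB1,NFKB2
4	DRD2	hsa-miR-9-3	V$RP58_01	AACATCTGGA	ZNF238
5	EGR3	hsa-miR-181b-1	V$IK3_01	TNYTGGGAATACC	IKZF1
6	EGR3	hsa-miR-20b	V$NGFIC_01	TGCGTRGGYGK	EGR1,EGR2,EGR3,EGR4
7	EGR3	hsa-miR-9-1	V$MZF1_02	KNNNKAGGGGNAA	MZF1
8	EGR3	hsa-miR-9-1	V$OCT_C	CTNATTTGCATAY	POU2F1,POU2F2
9	EGR3	hsa-miR-9-3	V$CREBP1_Q2	VGTGACGTMACN	CREB1,ATF2
10	GAD1	hsa-miR-9-2	V$OLF1_01	CDABTCCCYAGRGARBNKG	EBF1
11	GAD1	hsa-miR-9-3	V$NRSF_01	TTCAGCACCACGGACAGMGCC	REST
12	GRIN1	hsa-miR-195	V$EGR1_01,V$NGFIC_01	TGCGTRGGYGK	EGR1,EGR2,EGR3,EGR4
13	GRM7	hsa-miR-195	V$AHRARNT_01	KNNKNNTYGCGTGCMS	AHR,ARNT
14	GRM7	hsa-miR-195	V$NGFIC_01	TGCGTRGGYGK	EGR1,EGR2,EGR3,EGR4
15	GRM7	hsa-miR-20b	V$NGFIC_01	TGCGTRGGYGK	EGR1,EGR2,EGR3,EGR4
16	GRM7	hsa-miR-20b	V$TAL1BETAE47_01	AACAGATGKT	TCF3,TAL1
17	GRM7	hsa-miR-92a-2	V$NGFIC_01	TGCGTRGGYGK	EGR1,EGR2,EGR3,EGR4
18	GRM7	hsa-miR-92a-2	V$TAL1BETAE47_01	AACAGATGKT	TCF3,TAL1
19	HTR4	hsa-miR-195	V$AHRARNT_01	KNNKNNTYGCGTGCMS	AHR,ARNT
20	HTR4	hsa-miR-195	V$GCNF_01	TCAAGKTCAAGKTCA	NR6A1
21	MTHFR	hsa-miR-24-2	V$AHRARNT_02	KNNKNNTYGCGTGCMS	AHR,ARNT
22	NEUROG1	hsa-miR-20b	V$POU6F1_01	GCATAAWTTAT	POU6F1
23	NR4A2	hsa-miR-20b	V$PAX4_03	YCACCCB	PAX4
24	NR4A2	hsa-miR-212	V$BACH2_01	SRTGAGTCANC	BACH2
25	NR4A2	hsa-miR-212	V$CEBP_C	GWVTKNKGYAAKNSAYA	CEBPA
26	NR4A2	hsa-miR-212	V$CREB_01,V$CREBP1CJUN_01,V$CREBP1_Q2	TGACGTMA	CREB1,ATF2
27	NR4A2	hsa-miR-212	V$FREAC3_01	GTAAATAAACA	FOXC1
28	NTNG1	hsa-miR-9-3	V$PAX5_02	RRMSWGANWYCTNRAGCGKRACSRYNSM	PAX5
29	PDLIM5	hsa-miR-195	V$AHRARNT_01	KNNKNNTYGCGTGCMS	AHR,ARNT
30	RTN4	hsa-miR-212	V$BACH1_01,V$BACH2_01	SRTGAGTCA	BACH1,BACH2
31	TSNAX	hsa-miR-9-1	V$OCT_C	CTNATTTGCATAY	POU2F1,POU2F2
32	YWHAH	hsa-miR-195	V$EGR1_01	TGCGTRGGYGK	EGR1,EGR2,EGR3,EGR4
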