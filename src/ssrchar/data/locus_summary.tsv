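locus	library	genbank	motif	ta_c	forward	reverse	size_min	size_max	n_bands_focal	pic_focal	dp_focal	n_bands_all	pic_all	excluded
Pp-UNICAMP01	Lb-1	KR611535	(TG)8	60	GTGCAACACTATGACACCAG	ACAGTGCCCAATTGTTGT	173	181	4	0.64	0.7	5	0.7	0
Pp-UNICAMP02	Lb-1	KR611536	(CGCAC)3	51	CTCCACCAACGCCTTAC	TAGTCCATACCCTTTCGTTT	187	203	6	0.72	0.81	4	0.45	0
Pp-UNICAMP03	Lb-1	KR611537	(AC)8	60	TCTGCTAAGTTACCGCTCAT	ATGGATATGGAACTTGATGG	127	167	7	0.73	0.87	6	0.65	0
Pp-UNICAMP04	Lb-1	KR611538	(CA)7	60	TTGGATGCACACCAGTATAG	CCCTCTTCATTCTCATTCAG	133	151	3	0.41	0.69	7	0.66	0
Pp-UNICAMP05	Lb-1	KR611539	(GT)7	60	ATGGATATGGAACTTGATGG	CTACGGTCTGCTAAGTCACC	157	173	5	0.61	0.79	6	0.77	1
Pp-UNICAMP06	Lb-1	KR611540	(TC)8	51	GGTCCTGGTTGATTGATCT	CGGAGTTGAAGATGGACTC	155	169	7	0.73	0.88	8	0.75	0
Pp-UNICAMP07	Lb-1	KR611541	(TCT)4	65	AGCCTTGCCTCCAGTC	TTTCAGGTTACAGGTTGAGAG	222	258	6	0.66	0.74	6	0.69	0
Pp-UNICAMP08	Lb-1	KR611542	(GT)7	51	TGGGTTTGGGATAAGGATAG	GGTCCTCAACATGGGTAAC	144	170	12	0.66	1.0	14	0.69	0
Pp-UNICAMP09	Lb-1	KR611543	(AC)7	56	GCACAGGTAGAACCATTTCA	TATGGAACTTGATGGGATTG	228	260	8	0.81	0.85	6	0.78	0
Pp-UNICAMP10	Lb-1	KR611544	(CA)7	60	ATACCTTAGGATCCGCTTCA	CACTCTACCGGTCCATGATA	230	256	4	0.67	0.83	7	0.72	0
Pp-UNICAMP11	Lb-1	KR611545	(CA)7	60	GGAGAGATGAGACTCCCTTG	ACTCTCTACCGGTCCATGAT	232	266	6	0.72	0.86	5	0.69	0
Pp-UNICAMP12	Lb-2	KR611546	(GT)7	65	CGCGTGGACTACGATGG	AAACGCCCACTCATAATTCG	213	277	11	0.79	0.92	14	0.87	0
Pp-UNICAMP13	Lb-2	KR611547	(CA)3CG(CA)3	55	GGAGAGATGAGACTCCCTTGG	TCAAGGTGGACCAAACACAC	116	142	10	0.71	0.74	8	0.63	0
Pp-UNICAMP14	Lb-2	KR611548	(ACAT)4	63	GATGTTCCGCTCGTTTGATT	TGTTGGTCTCAGGCAGCTTAT	223	243	5	0.59	0.75	8	0.67	0
Pp-UNICAMP15	Lb-2	KR611549	(AG)17	55	ACAGCTTGGGCCTGACAC	GGCTGAACTCTCTTCCATTGTT	152	166	8	0.74	0.91	7	0.82	0
Pp-UNICAMP16	Lb-2	KR611550	(AC)6	55	GCACGTGTTCGTCATGAAAT	GCTTGGTCCCATGGATTATG	258	300	4	0.33	0.33	9	0.69	0
Pp-UNICAMP17	Lb-2	KR611551	(AG)17	57	TGACCGTGCCTAATCTCCTT	AAGTTTGCTCTTTCGCGTGT	147	191	15	0.87	0.99	13	0.86	0
Pp-UNICAMP18	Lb-2	KR611552	(GT)8CA(GT)7	65	CAGTCAACGACACGGGAAC	CCCAACCTAAATCACCTCACC	119	153	11	0.84	0.98	16	0.9	0
Pp-UNICAMP19	Lb-2	KR611553	(ATT)2(CA)8	57	CCCTCCCTCCATTTCACA	AGCTCGCAGAAGGCAAGA	203	241	13	0.87	0.97	15	0.88	0
Pp-UNICAMP20	Lb-2	KR611554	(GT)7	65	AAGAACTGCCAAGGAACT	GGAATAAACCTCAATAGGG	156	162	4	0.66	0.81	3	0.65	1
Pp-UNICAMP21	Lb-2	KR611555	(CT)14	55	GAGAGCCCAGACACAATGG	ATCAACACGCTGCTTCAGTG	145	205	14	0.88	0.99	17	0.9	0
Pp-UNICAMP22	Lb-3	KR611556	(CA)3CG(CA)3	65	CGCGGAGAGATGAGACT	TCAAGGTGGACCAAACAC	133	137	3	0.5	0.64	3	0.35	0
Pp-UNICAMP23	Lb-3	KR611557	(TA)5A(GT)23	55	AGCAGGAGATCATGGAG	TCCTACGTGAATGGCTAC	230	254	3	0.4	0.57	2	0.35	0
Pp-UNICAMP24	Lb-3	KR611558	(CA)9	63	TCTTGCATCATCCCGTATTG	GCTGCCTGGTCCACTCTC	179	215	10	0.83	0.96	10	0.8	0
Pp-UNICAMP25	Lb-3	KR611559	(AC)8	63	CGGACCGTCTTTATCTCCAA	GCTCCGATCCTCGAAATTCT	218	316	8	0.71	0.92	9	0.78	0
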