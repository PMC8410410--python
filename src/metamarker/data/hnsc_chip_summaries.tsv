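Name	Case_n	Case_mean	Case_sd	Cont_n	Cont_mean	Cont_sd	TP	FP	FN	TN
GSE11163	16	5.0060	2.9502	5	6.9577	3.0365	11	1	5	4
GSE22587	8	1.3000	5.5401	4	10.1731	6.4789	7	1	1	3
GSE28100	17	9.1189	2.1971	3	8.6146	3.0807	15	2	2	1
GSE31277	15	3.4416	0.2865	15	3.7763	0.1914	13	5	2	10
GSE32906	16	7.7991	2.3468	6	1.2160	1.4288	6	1	10	5
GSE32960	312	8.6397	0.3116	18	8.5930	0.3889	211	8	101	10
GSE34496	44	1.2115	0.3470	25	1.2232	0.3832	15	6	29	19
GSE36682	62	8.7352	0.4357	6	9.0868	0.0713	54	0	8	6
GSE41268	7	-1.1088	3.6207	3	-3.0293	0.3337	2	0	5	3
GSE43329	31	6.5909	0.2343	19	6.6317	0.0071	17	4	14	15
GSE45238	40	8.6857	2.4182	40	11.9760	2.0615	36	8	4	32
GSE46172	4	-2.8090	0.5321	4	3.9720	6.9307	3	0	1	4
GSE62819	5	4.2859	3.0773	5	3.7886	3.0131	5	4	0	1
GSE69002	3	2.9315	0.0689	4	2.9969	0.1152	3	2	0	2
GSE73171	3	1.5082	0.0336	3	1.8233	0.4318	3	1	0	2
GSE82064	35	5.9177	1.9298	12	6.9437	1.2942	14	0	21	12
GSE98463	8	1.8867	1.9029	8	2.0199	2.4693	8	7	0	1
GSE103931	30	5.0757	1.3494	19	5.9368	2.4772	29	14	1	5
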