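parameter	level	n	mean	sd
Tissue	HNSCC	484	5.139	3.274
Tissue	Normal	44	8.709	3.788
Age	>=60	267	5.027	3.259
Age	<60	214	5.253	3.275
Gender	Male	350	5.099	3.284
Gender	Female	132	5.255	3.267
Lymphovascular invasion	Yes	113	5.897	3.548
Lymphovascular invasion	No	211	5.223	3.314
Tumor status	With tumor	124	5.649	3.467
Tumor status	Tumor free	310	4.941	3.177
Histological grade	G3-G4	122	5.307	3.487
Histological grade	G1-G2	340	5.175	3.204
Pathologic stage	III-IV	376	4.924	3.239
Pathologic stage	I-II	106	5.915	3.308
T stage	T3-T4	299	4.814	3.069
T stage	T1-T2	172	5.702	3.515
N stage	N1-N3	239	5.055	3.268
N stage	N0	225	5.287	3.274
M stage	M1	5	2.968	1.602
M stage	M0	457	5.198	3.279
Margin status	Positive	55	5.246	3.219
Margin status	Negative	322	5.467	3.344
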