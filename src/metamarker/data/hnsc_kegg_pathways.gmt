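hsa05200	Pathways in cancer	BAX	E2F3	GNA13	KRAS	MET	BIRC5	COL4A1	CCNE2	IL24	FN1	HIF1A	ITGB4	MMP1	NRAS	PGF	STAT1	TPM3
hsa05205	Proteoglycans in cancer	CD44	KRAS	MET	CAV1	CAV2	FN1	FLNA	HIF1A	ITGB1	MSN	NRAS	PXN	PLAU	THBS1
hsa04151	PI3K-Akt signaling pathway	BCL2L11	KRAS	MET	COL4A1	CCNE2	FN1	ITGB1	IL2RA	NRAS	OSMR	PGF	SPP1	THBS1
hsa04510	Focal adhesion	MET	SHC1	CAV1	CAV2	COL4A1	FN1	FLNA	ITGB1	PXN	PGF	SPP1	THBS1
hsa05206	MicroRNAs in cancer	BCL2L11	CD44	E2F3	KRAS	MET	SHC1	CCNE2	GLS	NRAS	PLAU	THBS1
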