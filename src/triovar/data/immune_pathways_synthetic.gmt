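primary_immunodeficiency	synthetic curated immune pathway gene set	AIRE	CD40LG	IGLL1	RAG1	TAP1	TNFRSF13B	BTK	ICOS	CD19	IL2RG	JAK3	ADA	CD8A	ZAP70	RFXANK
jak_stat_signaling	synthetic curated immune pathway gene set	STAT5B	PIK3R1	PIK3CD	IL21R	IL10RA	IL10RB	IL17RA	JAK3	STAT3	IL2RG	GHR	EPOR	SOCS1
t_cell_receptor_signaling	synthetic curated immune pathway gene set	CD40LG	CTLA4	NFKB1	PIK3CD	PIK3R1	CD8A	ZAP70	LCK	FYN	CD28	ICOS
toll_like_receptor_signaling	synthetic curated immune pathway gene set	NFKB1	PIK3CD	TBK1	TIRAP	TLR4	TLR2	MYD88	IRAK4	IRF3
osteoclast_differentiation	synthetic curated immune pathway gene set	TNFSF11	TCIRG1	NCF2	NFKB1	FOSL2	JUNB
dna_repair	synthetic curated immune pathway gene set	BRCA1	BRCA2	ATM	RAD51	XRCC4	LIG4
cardiac_muscle_contraction	synthetic curated immune pathway gene set	MYH7	TNNT2	TPM1	ACTC1	MYL2
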