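# Per-patient autoimmune phenotype metadata for the 16-patient cohort.
# Category totals follow the published cohort description (6 SLE, 2
# Sjogren, 1 UCTD, 1 EGPA, 2 inflammatory arthritis, 1 each psoriatic
# arthritis / ITP / necrotizing lymphadenitis / pancytopenia; 10 female,
# 6 male). Patient-level links the
# cohort description states are kept (S2 psoriatic arthritis, S4 UCTD,
# F2 necrotizing lymphadenitis, F9 inflammatory arthritis with MDS,
# F10 young male with X-linked hyper-IgM, SLE in F1/F5/F6/F7/F8/F12);
# remaining assignments are synthetic, preserving the totals.
# phenotype_match_gene: clinician-asserted gene-specific phenotype flag
# (PP4); set only for F10, whose diagnosis was X-linked hyper-IgM.
patient	sex	phenotype	phenotype_match_gene
S1	male	Sjogren	.
S2	female	psoriatic_arthritis	.
S3	female	Sjogren	.
S4	female	UCTD	.
F1	female	SLE	.
F2	male	necrotizing_lymphadenitis	.
F3	female	EGPA	.
F4	female	ITP	.
F5	male	SLE	.
F6	female	SLE	.
F7	male	SLE	.
F8	female	SLE	.
F9	female	inflammatory_arthritis	.
F10	male	pancytopenia	CD40LG
F11	male	inflammatory_arthritis	.
F12	female	SLE	.
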