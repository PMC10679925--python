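# PID/CVID gene panel (subset of the literature/OMIM-derived panel used
# for candidate screening). Tag CVID_OMIM marks the known CVID genes from
# OMIM; everything else is tagged PID. MYB is deliberately NOT on the
# panel (oncogene, retained off-panel in reports).
LRBA	CVID_OMIM
CTLA4	CVID_OMIM
NFKB1	CVID_OMIM
TNFRSF13B	CVID_OMIM
IL21R	CVID_OMIM
RAG1	CVID_OMIM
CD40LG	CVID_OMIM
AIRE	PID
TNFSF11	PID
PSTPIP1	PID
CD8A	PID
PIK3R1	PID
PIK3CD	PID
MYSM1	PID
IL17RA	PID
TAP1	PID
IL10RA	PID
TIRAP	PID
TBK1	PID
IGLL1	PID
IL10RB	PID
GATA2	PID
TFRC	PID
KMT2D	PID
STAT5B	PID
NCF2	PID
TCIRG1	PID
BTK	PID
ICOS	PID
IL2RG	PID
JAK3	PID
STAT3	PID
DOCK8	PID
WAS	PID
ADA	PID
FOXP3	PID
AICDA	PID
UNG	PID
CD19	PID
CD81	PID
MS4A1	PID
NFKB2	PID
CARD11	PID
BLNK	PID
TCF3	PID
IKZF1	PID
PLCG2	PID
CD27	PID
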