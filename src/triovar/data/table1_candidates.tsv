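# Published candidate-variant table of a 16-patient CVID-with-autoimmunity
# WGS cohort (4 sporadic cases S1-S4, 12 trio families F1-F12).
# Transcribed columns: inheritance label, carrier ("normal") relative, gene,
# consequence, zygosity, AA/cDNA change, published ACMG class, population
# AFs (1000g-all | gnomAD), predictor verdicts (SIFT, PolyPhen2-HVAR,
# PolyPhen2-HDIV, MutationTaster), CADD phred, dbscSNV (ada, rf), GERP++.
# "." = absent/not reported; gerp "<2" = below-2 placeholder.
# chrom is the gene's real chromosome; positions and per-site QC are NOT in
# the published table and are synthesized downstream (see docs/methods.md).
patient	normal_name	heredity	gene	chrom	function	het_hom	change	published_acmg	af_1000g	af_gnomad	sift	pp_hvar	pp_hdiv	mt	cadd	dbscsnv_ada	dbscsnv_rf	gerp
S1	-	sporadic	RAG1	11	missense	het	p.R582G	VUS	.	.	D	B	B	D	12.19	.	.	2.13
S2	-	sporadic	LRBA	4	missense	hom	p.G359D	VUS	.	.	D	D	D	D	33	.	.	5.13
S3	-	sporadic	CTLA4	2	missense	het	p.P169A	VUS	0.000199681	0.00004471	D	B	P	D	12.47	.	.	<2
S3	-	sporadic	TNFRSF13B	17	missense	het	p.R84T	VUS	.	0.00002886	D	P	P	N	23	.	.	<2
S4	-	sporadic	AIRE	21	splicing	het	c.652+1G>T	VUS	0.000798722	0.00007992	.	.	.	.	.	1.0000	0.906	3.61
F1	F1_Dad	oligogene	TNFSF11	13	missense	het	p.D317E	VUS	.	.	D	P	D	D	.	.	.	<2
F1	F1_Mom	oligogene	PSTPIP1	15	missense	het	p.F388L	VUS	0.00239617	0.00069299	T	B	B	D	11.9	.	.	<2
F2	F2_Mom	oligogene	CD8A	2	missense	het	p.R174Q	VUS	.	0.00001222	D	D	D	N	33	.	.	3.92
F2	De novo	de_novo	PIK3R1	5	splicing	het	c.336+1G>A	Pathogenic	.	.	.	.	.	.	.	1.0000	0.938	5.1
F2	F2_Mom	oligogene	TNFRSF13B	17	missense	het	p.R84T	VUS	.	0.00002886	D	P	P	N	23	.	.	<2
F3	F3_Dad	oligogene	LRBA	4	missense	het	p.I2744T	VUS	0.000199681	0.00014432	D	P	P	D	24.5	.	.	5.8
F3	F3_Dad	oligogene	PIK3CD	1	missense	het	p.R408C	VUS	0.000599042	0.00018045	T	B	B	D	18.64	.	.	<2
F3	F3_Mom	oligogene	MYSM1	1	missense	het	p.P760L	VUS	0.000599042	0.00053214	D	D	D	D	28.4	.	.	5.26
F4	F4_Dad	oligogene	IL17RA	22	missense	het	p.I763V	VUS	0.00279553	0.00054611	D	B	P	N	19.51	.	.	4.55
F4	F4_Mom	oligogene	MYSM1	1	missense	het	p.P760L	VUS	0.000599042	0.00053214	D	D	D	D	28.4	.	.	5.26
F5	F5_Dad	oligogene	TAP1	6	stopgain	het	p.E46X	VUS	0.000199681	0.00010713	.	.	.	.	.	.	.	2.01
F5	F5_Mom	oligogene	IL21R	16	splicing	het	c.867+10_867+28dup	VUS	.	0.00000409	.	.	.	.	.	.	.	<2
F6	F6_Dad	oligogene	IL10RA	11	missense	het	p.P30L	VUS	.	0.00007214	D	B	P	N	12.45	.	.	3.08
F6	F6_Mom	oligogene	TIRAP	11	missense	het	p.D96N	VUS	0.00139776	0.00258373	D	D	D	D	29.4	.	.	5.41
F7	F7_Dad	oligogene	TBK1	12	missense	het	p.V421L	VUS	0.000199681	0.00001353	T	B	B	D	20.6	.	.	5.27
F7	F7_Son	oligogene	IGLL1	22	missense	het	p.T146M	VUS	0.00199681	0.00109133	D	P	P	N	.	.	.	<2
F8	F8_Dad	oligogene	LRBA	4	missense	het	p.N2364S	VUS	.	0.00000407	T	B	B	D	23.7	.	.	5.82
F8	F8_Mom	oligogene	IL10RA	11	missense	het	p.V233M	VUS	0.0071885	0.00199517	D	P	D	N	19.48	.	.	3.27
F8	F8_Mom	oligogene	IL10RB	21	missense	het	p.A44V	VUS	0.00119808	0.00038956	D	P	D	N	22.8	.	.	3.47
F9	De novo	de_novo	MYB	6	missense	het	p.E132K	VUS	.	.	D	D	D	D	31	.	.	5.81
F10	F10_Mom	recessive	CD40LG	X	missense	hom	p.H125P	Likely Pathogenic	.	.	D	P	D	D	25	.	.	5.5
F11	De novo	de_novo	GATA2	3	stopgain	het	p.R348X	Pathogenic	.	.	.	.	.	.	.	.	.	4.05
F11	F11_Mom	oligogene	TFRC	3	missense	het	p.D70A	VUS	.	0.00004117	T	B	B	D	10.37	.	.	<2
F11	F11_Mom	oligogene	NFKB1	4	missense	het	p.R533H	VUS	0.000199681	0.00053528	D	D	D	D	29	.	.	4.5
F11	F11_Dad	oligogene	KMT2D	12	missense	het	p.T245S	VUS	.	0.00000455	T	D	D	D	14.18	.	.	5.05
F11	De novo	de_novo	STAT5B	17	missense	het	p.N642H	VUS	.	0.00000406	T	D	D	D	24.3	.	.	5.33
F12	F12_Mom	oligogene	NCF2	1	missense	het	p.F116S	VUS	.	.	D	D	D	D	32	.	.	5.56
F12	F12_Dad	oligogene	TCIRG1	11	missense	het	p.R60W	VUS	0.00159744	0.00023873	D	D	D	D	33	.	.	4.9
F12	F12_Mom	oligogene	TIRAP	11	missense	het	p.E132K	VUS	0.00159744	0.00030251	D	D	D	D	29.3	.	.	5.67
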