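# smncopy locus registry, genome build GRCh37 (hg19), all coordinates 1-based inclusive.
# Gene intervals are RefSeq curated transcript spans (GRCh37), resolved manually from the
# UCSC refGene track, 2026-09. Discriminating-site alleles are the GRCh37 reference bases
# at the paired SMN1/SMN2 coordinates.
# site rows:    start = SMN1 coordinate, end = paired SMN2 coordinate, allele_smn1/allele_smn2 set.
# gene rows:    start/end = interval, info = role (target|control).
# variant rows: start/end = affected bases, info = variant class (SNV|deletion), alt_allele set
#               ("-" for a pure deletion).
record_type	name	chromosome	start	end	info	allele_smn1	allele_smn2	alt_allele
site	a	5	70247724	69372304	.	A	G	.
site	b	5	70247773	69372353	.	C	T	.
site	c	5	70247921	69372501	.	A	G	.
gene	SMN1	5	70220768	70248841	target	.	.	.
gene	SMN2	5	69345350	69373418	target	.	.	.
gene	ACAD9	3	128598332	128634910	control	.	.	.
gene	ATR	3	142168077	142297668	control	.	.	.
gene	CYP11B1	8	143953772	143961262	control	.	.	.
gene	EDNRB	13	78469616	78493903	control	.	.	.
gene	FASTKD2	2	207630080	207660913	control	.	.	.
gene	FOXN1	17	26833275	26865054	control	.	.	.
gene	HEXB	5	73935847	74018472	control	.	.	.
gene	IQCB1	3	121488610	121553926	control	.	.	.
gene	ITGA6	2	173292314	173371181	control	.	.	.
gene	IVD	15	40697686	40713512	control	.	.	.
gene	LMNA	1	156084461	156109880	control	.	.	.
gene	LRPPRC	2	44113363	44223144	control	.	.	.
gene	NTRK1	1	156785432	156851642	control	.	.	.
gene	PTEN	10	89623195	89728532	control	.	.	.
gene	RAB3GAP1	2	135809834	135928279	control	.	.	.
gene	RAPSN	11	47459307	47470730	control	.	.	.
gene	SIL1	5	138282408	138629246	control	.	.	.
gene	SLC22A5	5	131705444	131731306	control	.	.	.
gene	SLC35D1	1	67465014	67520080	control	.	.	.
gene	STIM1	11	3875756	4114440	control	.	.	.
variant	g.27134T>G	5	70247901	70247901	SNV	.	.	G
variant	g.27706_27707delAT	5	70248473	70248474	deletion	.	.	-
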