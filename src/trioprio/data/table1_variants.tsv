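family_id	sex	gene	chrom	pos	dbsnp_id	zygosity	consequence	hgvs_c	hgvs_p	ref	alt	support	cadd_phred	maf_gnomad	inheritance
F1	XY	RGPD5	chr2	109837829	rs1553471918	het	missense	c.4708G>A	p.Gly1570Arg	G	A	7	.	0.00002	de_novo
F1	XY	FAM90A26	chr4	9173181	rs1450748908	hom_alt	frameshift	c.10del	p.Cys4ValfsTer12	CG	C	.	.	0.00004	de_novo
F2	XY	FOXD4L1	chr2	113499585	rs201655302	het	missense	c.329A>C	p.Tyr110Ser	A	C	9	.	0.0001	de_novo
F2	XY	FAM170A	chr5	119634539	rs754719389	het	missense	c.791T>C	p.Met264Thr	T	C	7	.	0.00003	de_novo
F2	XY	DLG1	chr3	197090942	rs769502806	het	missense	c.1730G>A	p.Arg577Gln	G	A	6	.	0.00001	de_novo
F2	XY	ANKRD1	chr10	90917812	rs773773073	het	missense	c.472C>T	p.His158Tyr	C	T	11	.	0.00002	de_novo
F3	XX	TP63	chr3	189868614	rs886041251	het	missense	c.1027C>T	p.Arg343Trp	C	T	11	.	.	de_novo
F4	XX	NIPBL	chr5	37059093	NOVEL	het	frameshift	c.7617_7618del	p.Ser2540ProfsTer21	CAG	C	.	.	.	unknown
F5	XX	MYH3	chr17	10641317	rs121913617	het	missense	c.2015G>A	p.Arg672His	G	A	9	.	0.000008	de_novo
F6	XX	FGFR2	chr10	121520163	rs79184941	het	missense	c.755C>G	p.Ser252Trp	C	G	10	.	0.00002	unknown
F7	XY	TRIM74	chr7	72961358	rs199887265	het	stop_gained	c.487C>T	p.Arg163Ter	C	T	.	35	0.0004	de_novo
F7	XY	TRIM73	chr7	75403732	rs199982097	het	stop_gained	c.487C>T	p.Arg163Ter	C	T	.	35	0.0003	de_novo
F8	XY	PRDM9	chr5	23527360	NOVEL	hom_alt	frameshift	c.2272_2273insTG	p.Arg758LeufsTer182	A	ATG	.	.	.	de_novo
F9	XX	TP63	chr3	189867902	rs1205536026	het	missense	c.952C>T	p.Arg318Cys	C	T	11	.	0.000004	maternal
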