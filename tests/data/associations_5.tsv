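rsid	pmid	study_title	phenotype	phenotype_category	p_value	allele	maf	chrom	pos	region_type	gene
rs1041981	17554300	Genome-wide association study of 14000 cases	Myocardial infarction	Cardiovascular	1e-8	A	0.34	chr6	31540784	missense	LTA
rs7903146	17463246	Replication of genome-wide association signals	Type 2 diabetes	Metabolic	1e-6	T	0.28	chr10	114758349	intron	TCF7L2
rs9939609	17434869	A common variant in FTO	Body mass index	Anthropometric	1e-4	A	0.41	chr16	53820527	intron	FTO
rs429358	19734902	Genome-wide analysis of lipid traits	LDL cholesterol	Lipids	1e-3	C	0.15	chr19	45411941	missense	APOE
rs123456	20081858	Meta-analysis of fasting glucose	Fasting glucose	Metabolic	0.04	G	0.22	chr2	169763148	intergenic
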