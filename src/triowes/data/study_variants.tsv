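trio_id	gene	chrom	pos	ref	alt	mode	region	cdna_change	protein_change	gt_proband	gt_father	gt_mother	gt_sibling	genotype_printed	cadd_scaled	maf_local	maf_exac	maf_1000g	dbsnp_id	polyphen2	sift	mutationtaster	predictsnp2	roh	note
ASD-9	AGL	chr1	100340000	A	T	AD	splice_site	c.294-2A > T		het	het	hom_ref		A/T|A/T|A/A	24.9	0.0037	0	0					deleterious		
ASD-9	APC2	chr19	1456000	G	C	AD	splice_site	c.1207 + 3G > C		het	het	hom_ref		G/C|G/C|G/G	12.21	0	0.0002	0					deleterious		
ASD-16	MAN1B1	chr9	140000000	G	T	AR	exonic	c.1897G > T	p.V633F	hom_alt	het	het		T/T|G/T|G/T	26.5	0	0.00001656	0						chr9:139943549-141071552	
ASD-16	KCTD21	chr11	77600000	G	A	AR	exonic	c.152G > A	p.R51H	hom_alt	het	het		A/A|G/A|G/A	34	0	0.0001	0						chr11:74862391-77920563	
ASD-16	DUSP3	chr17	41850000	G	A	AR	exonic	c.439G > A	p.V147I	hom_alt	het	het		A/A|G/A|G/A	24	0	0.00002476	0						chr17:41332822-42248346	
ASD-16	CXORF30	chrX	35800000	G	A	X-linked	exonic	c.8943G > A	p.M2981I	het	hemi_alt	hom_ref		G/A|Hemi (A)|G/G	13.16	0	0	0				deleterious			female proband heterozygous; alias CFAP47
ASD-16	SSX3	chrX	48200000	C	A	X-linked	exonic	c.268C > A	p.R90S	het	hemi_alt	hom_ref		C/A|Hemi (A)|C/C	0.256	0.0008	0	0			deleterious				female proband heterozygous
ASD-16	AVPR2	chrX	153170000	ACGCCGCAGGGGA	A	X-linked	exonic	c.739–750 delCGCCGCAGGGGA	p.247-250del	het	hemi_alt	hom_ref		Het|Homo|WT		0.0009	0.0021	0.000529801				deleterious			father printed Homo on chrX, read as hemizygous alt; CADD not printed
ASD-17	CRY1	chr12	107380000	G	A	AR	exonic	c.272G > A	p.W91X	hom_alt	het	het	het	A/A|G/A|G/A|G/A (M)	40	0	0	0						chr12:99640557-107713511	
ASD-17	NLRP2	chr19	55480000	T	C	AR	exonic	c.523T > C	p.W175R	hom_alt	het	het	hom_ref	C/C|T/C|T/C|T/T (M)	0.119	0.0033	0.000008239	0		deleterious					
ASD-17	ACE2	chrX	15580000	C	A	X-linked	exonic	c.1235C > A	p.A412E	hemi_alt	hemi_ref	het	hemi_alt	Hemi (A)|Hemi (C)|C/A|Hemi (A) (M)	25.3	0.0038	0	0							
ASD-18	GLT8D1	chr3	52728000	CGAGT	C	AR	splice_site	c.811_812 + 2delGAGT	p.E271K	hom_alt	het	het		Homo|Het|Het	35	0.00168	0	0					deleterious	chr3:52720080-53269046	deletion spanning the exon/intron boundary; printed protein change nominal
ASD-18	DNAJC13	chr3	132180000	A	G	AR	exonic	c.5594A > G	p.N1865S	hom_alt	het	het		G/G|A/G|A/G	18.38	0.00042	0	0						chr3:129800895-133486958	
ASD-18	OR6C65	chr12	55720000	CA	C	AR	exonic	c.766delA	p.M256fs	hom_alt	het	het		Homo|Het|Het	27.6	0.00042	0.00001648	0	rs748626881					chr12:53647373-56089357	
ASD-18	HSPBP1	chr19	55770000	A	C	AR	exonic	c.1016A > C	p.E339A	hom_alt	het	het		C/C|A/C|A/C	26.7	0.00042	0	0						chr19:55525894-56047448	
ASD-18	ATP2B3	chrX	152800000	C	G	X-linked	exonic	c.1678C > G	p.P560A	hemi_alt	hemi_ref	het		Hemi (G)|Hemi (C)|C/G	3.822	0	0.0000129	0.00001144			deleterious				
ASD-19	MXRA5	chrX	3230000	C	T	X-linked	exonic	c.28C > T	p.L10F	hemi_alt	hemi_ref	het		Hemi (T)|Hemi (C)|C/T	24.1	0.0012	0	0							
ASD-19	ITIH6	chrX	54790000	A	G	X-linked	exonic	c.1153A > G	p.S385G	hemi_alt	hemi_ref	het		Hemi (G)|Hemi (A)|A/G	0.411	0.0021	0	0				deleterious			
ASD-19	KDM5B	chr1	202700000	C	A	De novo	exonic	c.2265C > A	p.Y755X	het	hom_ref	hom_ref		C/A|C/C|C/C	35	0	0.00003295	0							
ASD-21	NT5DC1	chr6	116500000	T	C	AR	exonic	c.1114T > C	p.S372P	hom_alt	het	het		C/C|T/C|T/C	28.1	0.0012	0	0						chr6:116442525-116574577	
ASD-21	TRIM9	chr14	51450000	G	A	AR	exonic	c.1643G > A	p.R548H	hom_alt	het	het		A/A|G/A|G/A	15.5	0	0.0000106	0	rs748897524					chr14:51225132-51716467	
ASD-24	GPKOW	chrX	48970000	C	T	X-linked	exonic	c.482C > T	p.A161V	hemi_alt	hemi_ref	het	hemi_alt	Hemi (T)|Hemi (C)|C/T|Hemi (T) (M)	9.839	0.0037	0.00001368	0	rs782015404	deleterious					
ASD-24	HTATSF1	chrX	135580000	T	G	X-linked	exonic	c.894T > G	p.F298L	hemi_alt	hemi_ref	het	hemi_alt	Hemi (G)|Hemi (T)|T/G|Hemi (G) (M)	24	0	0	0							
ASD-24	MOGS	chr2	74690000	GAA	G	De novo	exonic	c.832_833delAA	p.K278Efs*5	het	hom_ref	hom_ref	hom_ref	Het|WT|WT|WT (M)	27	0	0.000008359	0	rs370842409						
ASD-37	IDS	chrX	148560000	T	A	X-linked	exonic	c.525T > A	p.D175E	hemi_alt	hemi_ref	het	het	A/A|Hemi (T)|T/A|T/A (F)	12.51	0.0012	0	0			deleterious				male proband printed A/A on chrX, coerced hemizygous alt
ASD-38	ASB9	chrX	15270000	A	C	X-linked	exonic	c.310A > C	p.T104P	hemi_alt	hemi_ref	het		Hemi (C)|Hemi (A)|A/C	25.6	0.0008	0	0							
ASD-38	PDK3	chrX	24480000	A	G	X-linked	splice_site	c.248 + 3A > G	_	hemi_alt	hemi_ref	het		Hemi (G)|Hemi (A)|A/G	15.91	0.0021	0	0					deleterious		
ASD-38	PLP1	chrX	103040000	G	A	X-linked	exonic	c.328G > A	p.G110S	hemi_alt	hemi_ref	het		Hemi (A)|Hemi (G)|G/A	28.1	0	0	0							
ASD-39	NEB	chr2	152420000	T	C	AD	exonic	c.5939T > C	p.L1980S	het	hom_ref	het		T/C|T/T|T/C	25	0.00084	0.0003	0	rs375412223						
ASD-40	BOC	chr3	112990000	G	A	AR	exonic	c.1624G > A	p.G542R	hom_alt	het	het		A/A|G/A|G/A	28.6	0	0.000008237	0	rs752313669					chr3:112546306-113377505	
ASD-40	SSTR3	chr22	37000000	G	C	AR	exonic	c.724G > C	p.A242P	hom_alt	het	het		C/C|G/C|G/C	25.6	0	0.0003	0.000199681	rs577113986					chr22:32756744-37603744	
ASD-43	NGF	chr1	115830000	C	T	AR	exonic	c.361C > T	p.R121W	hom_alt	het	het		T/T|C/T|C/T	28.3	0.00084	0	0						chr1:114301335-116927468	
ASD-43	SUMF1	chr3	4420000	A	G	AR	exonic	c.710A > G	p.Q237R	hom_alt	het	het		G/G|A/G|A/G	26.3	0	0	0						chr3:439963-4856234	
ASD-58	MAOB	chrX	43630000	G	T	X-linked	exonic	c.392G > T	p.S131I	hemi_alt	hemi_ref	het		Hemi (T)|Hemi (G)|G/T	22.4	0.00042	0	0							
ASD-58	ZNF630	chrX	47920000	A	T	X-linked	exonic	c.77A > T	p.N26I	hemi_alt	hemi_ref	het		Hemi (T)|Hemi (A)|A/T	15.35	0	0	0							
ASD-58	PRODH2	chr19	36290000	G	C	De novo	exonic	c.625G > C	p.G209R	het	hom_ref	hom_ref		G/C|G/G|G/G	0.461	0	0.000008276	0	rs370842409			deleterious			
ASD-64	USP9X	chrX	40990000	A	G	X-linked	exonic	c.3803A > G	p.Y1268C	het	hemi_ref	het		A/G|Hemi (A)|A/G	25.2	0.00042	0	0							female proband heterozygous, carrier mother
ASD-64	RPS6KA6	chrX	83360000	A	G	X-linked	exonic	c.1535A > G	p.Q512R	het	hemi_alt	hom_ref		A/G|Hemi (G)|A/A	17.14	0.0025	0	0							female proband heterozygous
ASD-64	DDX26B	chrX	134640000	A	T	X-linked	exonic	c.1304A > T	p.E435V	het	hemi_alt	hom_ref		A/T|Hemi (T)|A/A	27.8	0.00084	0	0							female proband heterozygous; alias INTS6L
ASD-66	SEMG2	chr20	43850000	G	A	AD	exonic	c.500G > A	p.W167X	het	hom_ref	het		G/A|G/G|G/A	20.4	0.0058	0.000008241	0							
ASD-69	CELSR2	chr1	109600000	G	C	AR	exonic	c.8185G > C	p.D2729H	hom_alt	het	het	het	C/C|G/C|G/C|G/C (M)	25.8	0	0	0						chr1:109395105-109816176	
ASD-69	ITIH2	chr10	7750000	C	CTATT	AR	exonic	c.1863_1864insTATT	p.V622Yfs*17	hom_alt	het	het	hom_ref	Homo|Het|Het|WT (M)	24.3	0	0.00007417	0	rs748626881					chr10:3200292-13337588	
ASD-69	CEP152	chr15	49030000	A	C	AR	exonic	c.1718A > C	p.D573A	hom_alt	het	het	het	C/C|A/C|A/C|A/C (M)	11.88	0	0	0		deleterious				chr15:45392075-49284771	
ASD-69	ARSH	chrX	2930000	T	C	X-linked	exonic	c.1124T > C	p.I375T	hemi_alt	hemi_ref	het	hemi_alt	Hemi (C)|Hemi (T)|T/C|Hemi (C) (M)	22.3	0	0	0							
ASD-73	FGF5	chr4	81190000	C	T	AR	exonic	c.251C > T	p.S84L	hom_alt	het	het		T/T|C/T|C/T	24.3	0	0	0						chr4:80977078-88535895	
ASD-73	SMS	chrX	21940000	C	T	X-linked	exonic	c.424C > T	p.L142F	hemi_alt	hemi_ref	het		Hemi (T)|Hemi (C)|C/T	28.9	0	0	0							
ASD-73	FLNA	chrX	153580000	T	C	X-linked	exonic	c.7079T > C	p.V2360A	hemi_alt	hemi_ref	het		Hemi (C)|Hemi (T)|T/C	23.2	0.00042	0	0							
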