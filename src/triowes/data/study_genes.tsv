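gene	functional_category	sfari	autismkb	reported_asd_literature	reported_other_neuro	note
ACE2	Cell signaling cascade	0	0	1	0
AGL	Mitochondrial function/Energy metabolism	0	0	0	0
APC2	Neuronal function/Development	0	1	1	1	other-neuro: intellectual disability with Sotos-like features
ARSH	Unknown	0	1	1	0
ASB9	Protein quality control	0	1	1	0
ATP2B3	Cell signaling cascade	0	1	1	1	other-neuro: possible association with ID
AVPR2	Water homeostasis	0	1	1	1	other-neuro: NDI twins with ID
BOC	Neuronal function/Development	0	1	1	0	literature: candidate in 3q13.31 microdeletion patient with autism
CELSR2	Neuronal function/Development	0	0	0	1	other-neuro: schizophrenia
CEP152	Cell division or differentiation	0	1	1	0
CRY1	Sleep regulation	0	0	0	1	table text is phenotype commentary (sleep problems in autistic children), not a gene-level ASD report; encoded as no ASD evidence per the cohort tallies
CXORF30	Unknown	0	1	1	0	alias CFAP47
DDX26B	Unknown	0	0	0	0	alias INTS6L; one of 5 genes never reported in any human condition
DNAJC13	Protein quality control	0	0	0	1	other-neuro: Parkinson disease
DUSP3	Cell signaling cascade	0	1	1	0
FGF5	Neuronal function/Development	0	1	1	0
FLNA	Neuronal function/Development	0	1	1	0
GLT8D1	Unknown	0	0	0	0	one of 5 genes never reported in any human condition
GPKOW	Gene regulation (mRNA splicing)	0	1	1	0
HSPBP1	Protein quality control	0	1	1	0	literature report confounded by FX mutation and chr15 dup
HTATSF1	Gene regulation (mRNA splicing)	0	0	0	0	one of 5 genes never reported in any human condition
IDS	Protein quality control	0	1	1	0
ITIH2	Unknown	0	1	1	0
ITIH6	Unknown	0	0	0	0	one of 5 genes never reported in any human condition
KCTD21	Gene regulation/Protein quality control	0	0	0	1	other-neuro: schizophrenia; encoded as no ASD evidence (paired with PRODH2 as a schizophrenia gene in the cohort tallies; row tokens ambiguous in the source table)
KDM5B	Gene regulation/Cell differentiation	1	1	1	1	other-neuro: non-syndromic ID
MAN1B1	Protein quality control	0	1	1	1	other-neuro: ID
MAOB	Neuronal function/Development	1	1	0	1	synonymous variants reported; other-neuro: schizophrenia
MOGS	Immune responses	0	0	0	0
MXRA5	Neuronal function/Development	0	1	1	0	literature: three multiplex ASD families
NEB	Neuronal function/Development	0	0	0	1	other-neuro: ID and epilepsy
NGF	Neuronal function/Development	0	1	1	0
NLRP2	Immune responses	0	1	1	0
NT5DC1	Unknown	0	0	0	1	other-neuro: bipolar disorder
OR6C65	Olfaction	0	0	0	0	one of 5 genes never reported in any human condition; table text is phenotype commentary (impaired olfaction in ASD), not a gene-level report
PDK3	Mitochondrial function/Energy metabolism	0	1	1	0
PLP1	Neuronal function/Development	0	0	0	1	other-neuro: Xq22 microdeletion with ID
PRODH2	Neuronal function/Development	0	0	0	1	other-neuro: schizophrenia
RPS6KA6	Cell signaling cascade	0	1	1	1	other-neuro: possible role in nonspecific X-linked ID
SEMG2	Semen function	0	1	1	0
SMS	Neuronal function/Development	0	1	1	1	other-neuro: Snyder-Robinson X-linked ID
SSTR3	Neuronal function/Development	0	1	1	0
SSX3	Unknown	0	1	1	0
SUMF1	Neuronal function/Development	0	1	1	1	literature: structural variants in ASD; other-neuro: schizophrenia, multiple sclerosis
TRIM9	Neuronal function/Development	0	0	1	1	literature: putative causative gene in one ASD case; other-neuro: atypical psychosis
USP9X	Neuronal function/Development	0	1	1	1	other-neuro: X-linked ID
ZNF630	Unknown	0	1	1	0
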