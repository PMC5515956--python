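# Methods

## Scope and data model

The package implements the tertiary stage of a trio whole-exome workflow:
it consumes called genotypes (multi-sample VCF), a pedigree (PED), and a
per-variant annotation table produced upstream (ANNOVAR-style: gene, region
class, HGVS change strings, per-database allele frequencies, prediction-tool
calls, scaled CADD), and produces per-trio inheritance-model calls, a
prioritized candidate list with a per-variant filter audit trail, pairwise
relatedness reports, and cohort summaries. Read QC, alignment, variant
calling, annotation computation, and Sanger confirmation are out of scope;
their outputs are inputs here. Sanger status, when available, can be carried
as an external column and is never computed.

All records are normalized on ingestion: multi-allelic sites split into one
biallelic record per alternate (allele indices other than the kept
alternate count as reference, so summed dosage is conserved), and male
chrX/chrY calls outside the pseudoautosomal regions (PAR; hg19 PAR1
X:60,001–2,699,520, PAR2 X:154,931,044–155,260,560, configurable per build)
coerced to hemizygous however the VCF spells them. Coordinates are 1-based
closed per VCF; intervals (ROH, PAR) are half-open 0-based internally and
converted at the boundary.

## Inheritance models

Precedence is de novo > X-linked > autosomal recessive > autosomal
dominant. The first rule fires on any chromosome when the proband carries
an alternate absent from both parents. The X-linked rule applies to non-PAR
chrX only: hemizygous alternate in a male proband with a carrier mother;
homozygous alternate in a female proband with both parents carrying; and,
in the default `carrier_permissive` mode, a heterozygous female proband
with at least one carrier parent. The strict mode (`strict_homozygous`)
implements the classical homozygous-female rule instead. The permissive
default exists because the emulated study's printed per-trio table lists
heterozygous X-linked calls in both female probands, contradicting its own
written rule; the default reproduces the table, the strict mode the rule.

Recessive calls require proband homozygous-alternate with both parents
heterozygous, or a compound-heterozygous pair: two heterozygous proband
variants in one gene, one carried by the father only and one by the mother
only. All father-side × mother-side combinations are reported; variants
carried by both parents cannot be phased from a trio and are never paired.
Both members of a pair must survive prioritization to be reported (the
source description leaves this open; requiring both is the conservative
choice and is configurable only by editing the pipeline).

The dominant model is a fallback, applied per trio only when no candidate
of the three main models survives the full prioritization. The decision is
made after filtering, not after raw classification: a de novo call that
fails the rarity filter does not block the dominant branch. This is the
only reading that yields dominant-only findings in trios whose other
candidates were filtered away.

Genotype configurations impossible under Mendelian transmission (for
example proband homozygous-alternate with a homozygous-reference parent)
are flagged `mendelian_consistent=False` and left unclassified rather than
silently dropped — in a real run these are exactly the calls worth manual
review or confirmation. A single new allele (the canonical de novo
signature) counts as consistent, so an error-free simulated cohort reports
zero inconsistencies. Sibling genotypes never influence classification;
they are retained for post-hoc segregation annotation only.

The full mapping over all 27 autosomal and 12 male-X genotype
configurations is committed as a hand-enumerated truth table
(`tests/data/classification_truth.tsv`) and the classifier is tested
against it exhaustively.

## Prioritization

Stage order: region trim → rarity → deleteriousness consensus → gene
flagging.

* **Region trim** keeps `exonic` and `splice_site` regions (configurable
  whitelist) and drops synonymous changes.
* **Rarity** drops a variant iff any recorded database frequency (local
  panel, ExAC, 1000 Genomes, dbSNP) reaches `maf_threshold` (default 1%).
  An absent frequency means "not observed in that database" and passes, as
  does a recorded zero. dbSNP membership alone never excludes: the
  published cohort retains nine dbSNP-identified variants with
  sub-threshold frequencies, so membership is kept as novelty metadata
  only.
* **Deleteriousness consensus** counts votes: each tool (PolyPhen-2, SIFT,
  MutationTaster, PredictSNP2) calling deleterious contributes one, and a
  scaled CADD at or above `cadd_cutoff` (default 15, the conventional
  "top ~3% most deleterious" phred-scaled rank) contributes one. A variant
  is retained with at least `min_deleterious_tools` votes (default 1).
  CADD never vetoes other tools; splice-site variants can qualify through
  PredictSNP2 alone. Variants with neither predictions nor a CADD score are
  dropped as unpredicted.

Variants annotated to multiple genes should be duplicated per gene upstream
of per-gene logic; the annotation table is keyed by (chrom, pos, ref, alt)
and carries a single gene per row.

## Effect classification from HGVS strings

Effects are classified from the annotation's cDNA/protein change strings,
not recomputed from transcripts: intronic offsets within ±50 of an exon
edge (`c.294-2A > T`, `c.1207 + 3G > C`) → splice site, taking precedence
over any printed protein change (deletions spanning a splice donor can
carry a nominal protein change); `fs` → frameshift; terminal `X`/`*`/`Ter`
→ nonsense; `del` of whole codons without frameshift → in-frame deletion;
single-residue substitutions → missense or synonymous. Typeset en-dashes
denote position ranges and are never read as offsets; unparseable strings
degrade to `other` with a warning.

## Relatedness

Three estimators over a sites × samples dosage matrix:

* **A_jk** (standardized genotype cross-products): expectation 0 for
  unrelated pairs, 0.5 for parent–offspring, 1 for duplicates. Sites with
  allele frequency exactly 0 or 1 are excluded. Frequencies come from the
  annotation table when available, otherwise they are estimated from the
  cohort's non-missing calls — with trio-only cohorts the estimate is noisy
  and the ranking criterion below is the reliable signal.
* **Shared homozygosity**: the count of common sites (minor allele
  frequency above `sharedhom_maf_floor`, default 1%) at which both samples
  are homozygous for the same alternate. Homozygous-reference sharing is
  not counted (the alternative reading is noted but not implemented). The
  verdict rule compares the count with μ + k·σ of unrelated-pair sharing.
  The published constants are μ=123, σ=25; the verdict sentence as printed
  ("less than 25 SD above the mean") is not arithmetically coherent, so the
  default is k=1 (threshold 148) with μ, σ, k all configurable. The
  absolute threshold is meaningful only at exome-scale site counts; on
  small panels use the ranking criterion.
* **KING robust kinship**: expectation 0.25 parent–offspring, 0.5
  duplicates, ~0 (negative allowed) unrelated.

Missing genotypes are handled by pairwise-complete deletion per site.
Hemizygous male X sites are excluded by default (none of the estimators
defines them); optional inclusion codes them 0/2. Trio verification
reports father–proband, mother–proband and father–mother, and confirms
parenthood when both parent–child pairs outrank the parent–parent pair
under every method — the ranking criterion, which is what the emulated
study actually checked.

## Synthetic cohorts

The generator emulates the study conditions: 19 singleton trios, 17/19
male probands, 9/19 consanguineous families, background sites at
Uniform(0.05, 0.5) allele frequencies (8% on chrX), founders drawn with an
inbreeding coefficient f (default 0.0625, first-cousin offspring) that
copies a shared ancestral allele — producing the Hardy–Weinberg
heterozygosity deficit f·2p(1−p) — and probands generated by sex-aware
Mendelian transmission. Planted variants force the genotype configuration
of their model; `study_like_spec()` reproduces the published per-trio
layout (3 de novo / 4 dominant / 21 X-linked / 19 recessive, dominant
plants only in trios with no other findings, two trios with none). Decoy
plants each violate exactly one filter (common frequency, benign
predictions, intronic region) and carry their intended fate in the truth
table. Genotyping error is a per-genotype uniform flip to a different
state. The default background of 300–400 sites per cohort keeps end-to-end
runs fast while leaving every filter exercised; estimator calibration uses
10,000-site matrices generated directly as dosage arrays.

What the simulator does **not** model: read-level errors, realistic human
allele-frequency spectra, linkage disequilibrium, transcript structure
(synthetic genes are positional blocks), imprinting, mosaicism, and
mitochondrial inheritance. Passing recovery tests therefore demonstrates
the correctness of the classification and filtering logic under the
stated genotype model, not robustness to real-exome artifacts.

## The packaged fixture

The emulated study deposited no raw data; its cohort exists only as
printed tables. The fixture encodes them: 19 trios, 47 validated variants
with per-member genotype states, printed inheritance modes, scaled CADD,
per-database frequencies, dbSNP identifiers and ROH intervals, plus
per-gene evidence flags and manually curated functional categories.
Genomic positions are synthetic keys (not printed in the source), placed
on each gene's true chromosome, inside the printed ROH interval where one
exists and outside the PARs for chrX genes. Rows whose printed genotypes
or flags required an interpretation (a father printed "Homo" on chrX, read
as hemizygous; phenotype commentary in an evidence column, read as
no gene-level evidence; a per-family consanguinity flag completed to match
the stated cohort total) carry per-row provenance notes in the TSVs.
Per-tool prediction calls are not printed per variant; the fixture
reconstructs minimal calls consistent with each variant's retention
(splice-site rows get the footnoted PredictSNP2 "Deleterious"; rows whose
scaled CADD is below the default cutoff get one plausible tool call).
Reproducing the cohort numbers from the fixture demonstrates that the
pipeline logic maps the printed genotypes to the printed conclusions; it
is not a re-analysis of the underlying exomes. File integrity is enforced
with SHA-256 checksums at load time.

## Numerical and degenerate-input choices

Percentages are integer-rounded half-up (36/47 → 77%, 4/47 → 9%).
Estimators raise on empty usable-site sets (all-monomorphic for A_jk, no
heterozygotes for kinship) rather than returning NaN; trio verification
degrades per method without aborting the others. Filter thresholds are
inclusive on the dropping side (a frequency exactly at 1% is dropped; a
CADD exactly at the cutoff votes). Empty per-trio results are valid
outcomes. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical spec + seed reproduces
byte-identical simulator output.

## Known limitations

No Y-chromosome or mitochondrial models, no imprinting or penetrance
modeling, no liftover, no IBD-segment detection or pedigree reconstruction
beyond the trio flag, no population-structure correction in relatedness,
and no pathway enrichment statistics (category membership counts only).
The dominant fallback is a per-trio binary decision; ranking multiple
dominant candidates is left to the analyst.
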