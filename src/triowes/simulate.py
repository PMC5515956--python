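"""Synthetic trio cohorts with the statistical structure the analysis assumes.

Founder genotypes are drawn from population allele frequencies (optionally
with an inbreeding coefficient f that copies a shared ancestral allele, the
homozygosity-enrichment signature of consanguinity), probands inherit by
Mendelian transmission (sex-aware on chrX), and variants of each
inheritance class are planted with the genotype configuration their model
demands.  A truth table records every planted variant's intended model and
pipeline fate, so end-to-end recall and precision are computable without
manual inspection.

The generator's defaults mirror the emulated study: 19 singleton trios,
17/19 male probands, 9/19 consanguineous families, and a per-trio plant
layout reproducing the published model counts (3 de novo / 4 dominant /
21 X-linked / 19 recessive).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formats import write_annotations, write_pedigree, write_vcf
from .model import (
    AnnotationBundle,
    GenotypeCall,
    Individual,
    Prediction,
    Region,
    Role,
    Sex,
    TrioPedigree,
    VariantRecord,
)
from .relatedness import GenotypeMatrix

__all__ = [
    "SimSpec",
    "TruthRecord",
    "SimulatedCohort",
    "simulate_cohort",
    "study_like_spec",
    "inject_errors",
    "simulate_pair",
    "simulate_trio_matrix",
    "sample_founder_dosages",
    "write_cohort",
]

PLANT_TYPES = (
    "de_novo",
    "ar_homozygous",
    "ar_compound_het",
    "ad",
    "x_linked_male",
    "x_linked_female",
    "decoy_common",
    "decoy_benign",
    "decoy_intronic",
)

#: Intended pipeline fate per plant type.
PLANT_FATE = {
    "de_novo": "retained",
    "ar_homozygous": "retained",
    "ar_compound_het": "retained",
    "ad": "retained",
    "x_linked_male": "retained",
    "x_linked_female": "retained",
    "decoy_common": "dropped:rarity_filter",
    "decoy_benign": "dropped:deleterious_consensus",
    "decoy_intronic": "dropped:region_trim",
}

PLANT_MODEL = {
    "de_novo": "de_novo",
    "ar_homozygous": "autosomal_recessive",
    "ar_compound_het": "autosomal_recessive",
    "ad": "autosomal_dominant",
    "x_linked_male": "x_linked",
    "x_linked_female": "x_linked",
    "decoy_common": "de_novo",
    "decoy_benign": "de_novo",
    "decoy_intronic": "de_novo",
}


@dataclass
class SimSpec:
    """Parameters of one simulated cohort.

    ``plants`` gives per-trio plant counts applied to every trio;
    ``plant_layout`` (one dict per trio) overrides it for heterogeneous
    cohorts.  X-linked plant types require a proband of the matching sex in
    the receiving trio.  The same seed and spec always reproduce identical
    output.
    """

    n_trios: int = 19
    n_background_sites: int = 400
    af_low: float = 0.05
    af_high: float = 0.5
    plants: dict[str, int] = field(
        default_factory=lambda: {"de_novo": 1, "ar_homozygous": 1, "ar_compound_het": 1}
    )
    plant_layout: Optional[list[dict[str, int]]] = None
    genotyping_error_rate: float = 0.0
    consanguinity_f: float = 0.0625
    consanguineous_fraction: float = 9 / 19
    proband_sex_ratio: float = 17 / 19
    x_background_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("genotyping_error_rate", self.genotyping_error_rate),
            ("consanguinity_f", self.consanguinity_f),
            ("consanguineous_fraction", self.consanguineous_fraction),
            ("proband_sex_ratio", self.proband_sex_ratio),
        ):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_trios < 1 or self.n_background_sites < 0:
            raise ValueError("cohort sizes must be non-negative (and >= 1 trio)")
        layouts = self.plant_layout or [self.plants] * self.n_trios
        if len(layouts) != self.n_trios:
            raise ValueError("plant_layout must provide one entry per trio")
        for layout in layouts:
            for key, count in layout.items():
                if key not in PLANT_TYPES:
                    raise ValueError(f"unknown plant type {key!r}")
                if count < 0:
                    raise ValueError("plant counts must be >= 0")

    def layout_for(self, trio_index: int) -> dict[str, int]:
        layouts = self.plant_layout or [self.plants] * self.n_trios
        return layouts[trio_index]


@dataclass(frozen=True)
class TruthRecord:
    key: tuple[str, int, str, str]
    trio_id: str
    model: str
    fate: str


@dataclass
class SimulatedCohort:
    spec: SimSpec
    trios: list[TrioPedigree]
    variants_by_trio: dict[str, list[VariantRecord]]
    annotations: dict[tuple[str, int, str, str], AnnotationBundle]
    truth: list[TruthRecord]
    error_count: int = 0


def sample_founder_dosages(rng: np.random.Generator, freqs: np.ndarray, f: float) -> np.ndarray:
    """Draw diploid dosages for one founder.

    With probability ``f`` per site both alleles are copies of one ancestral
    draw (dosage 0 or 2); otherwise two independent Bernoulli(p) alleles.
    At f=0 this is Hardy-Weinberg; at f>0 heterozygosity drops by
    f * 2p(1-p).
    """
    n = len(freqs)
    a1 = (rng.random(n) < freqs).astype(np.int8)
    a2 = (rng.random(n) < freqs).astype(np.int8)
    ibd = rng.random(n) < f
    a2 = np.where(ibd, a1, a2)
    return a1 + a2


def _transmit(rng: np.random.Generator, dosage: np.ndarray) -> np.ndarray:
    """One allele from a diploid parent per site: het transmits a coin flip."""
    allele = np.where(dosage == 1, (rng.random(len(dosage)) < 0.5).astype(np.int8), dosage // 2)
    return allele.astype(np.int8)


def _dosage_to_call(d: int) -> GenotypeCall:
    return (GenotypeCall((0, 0)), GenotypeCall((0, 1)), GenotypeCall((1, 1)))[d]


_BASES = ("A", "C", "G", "T")


def simulate_cohort(spec: SimSpec) -> SimulatedCohort:
    """Generate a trio cohort with planted variants and a truth table."""
    rng = np.random.default_rng(spec.seed)

    n_x = int(round(spec.n_background_sites * spec.x_background_fraction))
    n_auto = spec.n_background_sites - n_x
    chroms = [f"chr{1 + i % 22}" for i in range(n_auto)] + ["chrX"] * n_x
    positions: dict[str, int] = {}
    sites = []
    for chrom in chroms:
        positions[chrom] = positions.get(chrom, 5_000_000) + 10_000
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append((chrom, positions[chrom], _BASES[ref], _BASES[alt]))
    freqs = rng.uniform(spec.af_low, spec.af_high, size=spec.n_background_sites)

    n_cons = int(round(spec.consanguineous_fraction * spec.n_trios))
    n_male = int(round(spec.proband_sex_ratio * spec.n_trios))
    if any(spec.layout_for(i).get("x_linked_female", 0) for i in range(spec.n_trios)) and n_male == spec.n_trios:
        raise ValueError("x_linked_female plants require at least one female proband")

    # Deterministic sex / consanguinity assignment honoring the layouts:
    # trios demanding female-X plants get female probands first.
    sexes = [Sex.MALE] * spec.n_trios
    females_needed = [
        i for i in range(spec.n_trios) if spec.layout_for(i).get("x_linked_female", 0) > 0
    ]
    n_female = spec.n_trios - n_male
    if len(females_needed) > n_female:
        raise ValueError("more trios demand x_linked_female plants than female probands exist")
    for i in females_needed:
        sexes[i] = Sex.FEMALE
    remaining = n_female - len(females_needed)
    for i in range(spec.n_trios):
        if remaining == 0:
            break
        if sexes[i] is Sex.MALE and not spec.layout_for(i).get("x_linked_male", 0):
            sexes[i] = Sex.FEMALE
            remaining -= 1

    trios: list[TrioPedigree] = []
    variants_by_trio: dict[str, list[VariantRecord]] = {}
    annotations: dict[tuple[str, int, str, str], AnnotationBundle] = {}
    truth: list[TruthRecord] = []
    error_count = 0
    plant_pos = 200_000_000  # beyond background positions, unique per plant site
    gene_counter = 0

    x_mask = np.array([c == "chrX" for c, *_ in sites])

    for t in range(spec.n_trios):
        tid = f"SIM-{t + 1}"
        f_coef = spec.consanguinity_f if t < n_cons else 0.0
        sex = sexes[t]
        trio = TrioPedigree(
            family_id=tid,
            proband=Individual(f"{tid}-P", sex, Role.PROBAND, affected=True),
            father=Individual(f"{tid}-F", Sex.MALE, Role.FATHER),
            mother=Individual(f"{tid}-M", Sex.FEMALE, Role.MOTHER),
        )
        trios.append(trio)

        father_d = sample_founder_dosages(rng, freqs, f_coef)
        mother_d = sample_founder_dosages(rng, freqs, f_coef)
        # fathers are hemizygous on X
        father_d = np.where(x_mask, (father_d > 0).astype(np.int8), father_d)
        from_father = _transmit(rng, father_d)
        from_mother = _transmit(rng, mother_d)
        if sex is Sex.MALE:
            child_d = np.where(x_mask, from_mother, from_father + from_mother)
        else:
            # daughters receive the father's single X allele
            child_d = np.where(x_mask, father_d + from_mother, from_father + from_mother)

        records: list[VariantRecord] = []
        for i, (chrom, pos, ref, alt) in enumerate(sites):
            on_x = x_mask[i]
            genotypes = {}
            for sid, dosage, hemi in (
                (trio.father.id, int(father_d[i]), on_x),
                (trio.mother.id, int(mother_d[i]), False),
                (trio.proband.id, int(child_d[i]), on_x and sex is Sex.MALE),
            ):
                if hemi:
                    genotypes[sid] = GenotypeCall((1 if dosage > 0 else 0,))
                else:
                    genotypes[sid] = _dosage_to_call(dosage)
            records.append(VariantRecord(chrom, pos, ref, alt, genotypes))
            key = (chrom, pos, ref, alt)
            if key not in annotations:
                annotations[key] = AnnotationBundle(
                    gene=f"BG{i}",
                    region=Region.EXONIC,
                    maf={"local": round(float(freqs[i]), 6), "ExAC": round(float(freqs[i]), 6)},
                )

        # --- plants -------------------------------------------------------
        layout = spec.layout_for(t)
        for plant_type in PLANT_TYPES:
            for _ in range(layout.get(plant_type, 0)):
                gene_counter += 1
                gene = f"PLANT{gene_counter}"
                n_sites_for_plant = 2 if plant_type == "ar_compound_het" else 1
                plant_records = []
                for s in range(n_sites_for_plant):
                    plant_pos += 10_000
                    ref, alt = "A", "G"
                    chrom = "chrX" if plant_type.startswith("x_linked") else "chr2"
                    genotypes = _plant_genotypes(plant_type, s, trio, sex)
                    rec = VariantRecord(chrom, plant_pos, ref, alt, genotypes)
                    plant_records.append(rec)
                    annotations[rec.key] = _plant_annotation(plant_type, gene, s)
                    truth.append(
                        TruthRecord(rec.key, tid, PLANT_MODEL[plant_type], PLANT_FATE[plant_type])
                    )
                records.extend(plant_records)

        if spec.genotyping_error_rate > 0:
            records, flipped = inject_errors(
                records, spec.genotyping_error_rate, rng=rng
            )
            error_count += flipped
        records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
        variants_by_trio[tid] = records

    return SimulatedCohort(spec, trios, variants_by_trio, annotations, truth, error_count)


def _plant_genotypes(
    plant_type: str, site_index: int, trio: TrioPedigree, sex: Sex
) -> dict[str, GenotypeCall]:
    P, F, M = trio.proband.id, trio.father.id, trio.mother.id
    het = GenotypeCall((0, 1))
    hom_ref = GenotypeCall((0, 0))
    hom_alt = GenotypeCall((1, 1))
    hemi_ref = GenotypeCall((0,))
    hemi_alt = GenotypeCall((1,))
    if plant_type in ("de_novo", "decoy_common", "decoy_benign", "decoy_intronic"):
        return {P: het, F: hom_ref, M: hom_ref}
    if plant_type == "ar_homozygous":
        return {P: hom_alt, F: het, M: het}
    if plant_type == "ar_compound_het":
        if site_index == 0:
            return {P: het, F: het, M: hom_ref}
        return {P: het, F: hom_ref, M: het}
    if plant_type == "ad":
        return {P: het, F: het, M: hom_ref}
    if plant_type == "x_linked_male":
        if sex is not Sex.MALE:
            raise ValueError(f"x_linked_male plant in female-proband trio {trio.family_id}")
        return {P: hemi_alt, F: hemi_ref, M: het}
    if plant_type == "x_linked_female":
        if sex is not Sex.FEMALE:
            raise ValueError(f"x_linked_female plant in male-proband trio {trio.family_id}")
        return {P: hom_alt, F: hemi_alt, M: het}
    raise ValueError(plant_type)


def _plant_annotation(plant_type: str, gene: str, site_index: int) -> AnnotationBundle:
    """Annotation consistent with the plant's intended fate."""
    base = dict(
        gene=gene,
        region=Region.EXONIC,
        cdna_change=f"c.{100 + site_index}A > G",
        protein_change=f"p.K{34 + site_index}E",
        maf={"ExAC": 0.0002},
        cadd_scaled=25.0,
    )
    if plant_type == "decoy_common":
        base["maf"] = {"ExAC": 0.05}
    elif plant_type == "decoy_benign":
        base["cadd_scaled"] = 3.0
        base["predictions"] = {"sift": Prediction.BENIGN}
    elif plant_type == "decoy_intronic":
        base["region"] = Region.INTRONIC
        base["cdna_change"] = None
        base["protein_change"] = None
    ann = AnnotationBundle(**base)
    if base.get("cdna_change"):
        from .hgvs import parse_hgvs_effect

        ann.effect = parse_hgvs_effect(base["cdna_change"], base["protein_change"])
    return ann


def inject_errors(
    records: list[VariantRecord],
    rate: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantRecord], int]:
    """Replace each genotype with a random different one with probability ``rate``.

    Hemizygous calls flip ref↔alt; diploid calls move to one of the two
    other diploid states.  Returns the perturbed records and the number of
    injected errors.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rate == 0.0:
        return list(records), 0
    out: list[VariantRecord] = []
    flipped = 0
    diploid_states = [GenotypeCall((0, 0)), GenotypeCall((0, 1)), GenotypeCall((1, 1))]
    for rec in records:
        genotypes = dict(rec.genotypes)
        for sid, call in genotypes.items():
            if call.missing or rng.random() >= rate:
                continue
            flipped += 1
            if call.hemizygous:
                genotypes[sid] = GenotypeCall((1 - call.alleles[0],))
            else:
                choices = [g for g in diploid_states if g.alleles != call.alleles]
                genotypes[sid] = choices[int(rng.integers(len(choices)))]
        out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt, genotypes, rec.quality))
    return out, flipped


def simulate_pair(
    relationship: str,
    n_sites: int,
    af_low: float = 0.05,
    af_high: float = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Two-sample genotype matrix under a named relationship.

    ``relationship`` is one of parent_offspring, unrelated, duplicate,
    full_sib; genotypes follow random mating at Uniform(af_low, af_high)
    allele frequencies.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(af_low, af_high, size=n_sites)
    if relationship == "unrelated":
        a = sample_founder_dosages(rng, p, 0.0)
        b = sample_founder_dosages(rng, p, 0.0)
    elif relationship == "duplicate":
        a = sample_founder_dosages(rng, p, 0.0)
        b = a.copy()
    elif relationship == "parent_offspring":
        a = sample_founder_dosages(rng, p, 0.0)
        b = _transmit(rng, a) + (rng.random(n_sites) < p).astype(np.int8)
    elif relationship == "full_sib":
        father = sample_founder_dosages(rng, p, 0.0)
        mother = sample_founder_dosages(rng, p, 0.0)
        a = _transmit(rng, father) + _transmit(rng, mother)
        b = _transmit(rng, father) + _transmit(rng, mother)
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    sites = [("chr1", 1000 + i, "A", "G") for i in range(n_sites)]
    dosages = np.stack([a, b], axis=1)
    return GenotypeMatrix(["A", "B"], sites, dosages, p)


def simulate_trio_matrix(
    n_sites: int,
    seed: int = 0,
    af_low: float = 0.05,
    af_high: float = 0.5,
    proband: str = "true_child",
) -> GenotypeMatrix:
    """Autosomal dosage matrix for a father/mother/child triple.

    ``proband`` selects the child column: a true offspring of the two
    founders, an ``unrelated`` individual, or a ``duplicate`` of the father
    (a sample-swap scenario).  Columns are named F, M, P.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(af_low, af_high, size=n_sites)
    father = sample_founder_dosages(rng, p, 0.0)
    mother = sample_founder_dosages(rng, p, 0.0)
    if proband == "true_child":
        child = _transmit(rng, father) + _transmit(rng, mother)
    elif proband == "unrelated":
        child = sample_founder_dosages(rng, p, 0.0)
    elif proband == "duplicate":
        child = father.copy()
    else:
        raise ValueError(f"unknown proband kind {proband!r}")
    sites = [("chr1", 1000 + i, "A", "G") for i in range(n_sites)]
    dosages = np.stack([father, mother, child], axis=1)
    return GenotypeMatrix(["F", "M", "P"], sites, dosages, p)


def study_like_spec(seed: int = 0, n_background_sites: int = 400) -> SimSpec:
    """A cohort spec mirroring the emulated study's published layout:
    19 trios with per-trio plants reproducing the 3/4/21/19 model counts,
    dominant plants only in trios with no other findings, and two trios
    with no plants at all."""
    layout = [
        {"ad": 2},  # dominant-only trio
        {"ar_homozygous": 3, "x_linked_female": 3},
        {"ar_homozygous": 2, "x_linked_male": 1},
        {"ar_homozygous": 4, "x_linked_male": 1},
        {"x_linked_male": 2, "de_novo": 1},
        {"ar_homozygous": 2},
        {"x_linked_male": 2, "de_novo": 1},
        {"x_linked_male": 1},
        {"x_linked_male": 3},
        {"ad": 1},
        {"ar_homozygous": 2},
        {"ar_homozygous": 2},
        {},  # no candidate genes
        {},  # no candidate genes
        {"x_linked_male": 2, "de_novo": 1},
        {"x_linked_female": 3},
        {"ad": 1},
        {"ar_homozygous": 3, "x_linked_male": 1},
        {"ar_homozygous": 1, "x_linked_male": 2},
    ]
    return SimSpec(
        n_trios=19,
        n_background_sites=n_background_sites,
        plant_layout=layout,
        seed=seed,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | os.PathLike) -> dict[str, list[str]]:
    """Write one VCF + PED per trio, a cohort annotation TSV and truth TSV."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, list[str]] = {"vcf": [], "ped": []}
    for trio in cohort.trios:
        vcf_path = os.path.join(outdir, f"{trio.family_id}.vcf")
        ped_path = os.path.join(outdir, f"{trio.family_id}.ped")
        write_vcf(
            vcf_path,
            cohort.variants_by_trio[trio.family_id],
            [m.id for m in trio.members],
        )
        write_pedigree(ped_path, trio)
        paths["vcf"].append(vcf_path)
        paths["ped"].append(ped_path)
    ann_path = os.path.join(outdir, "annotations.tsv")
    write_annotations(ann_path, cohort.annotations)
    truth_path = os.path.join(outdir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\ttrio_id\tmodel\tfate\n")
        for rec in cohort.truth:
            chrom, pos, ref, alt = rec.key
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{rec.trio_id}\t{rec.model}\t{rec.fate}\n")
    paths["annotations"] = [ann_path]
    paths["truth"] = [truth_path]
    return paths
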