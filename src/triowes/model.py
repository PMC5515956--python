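"""Core domain types shared by every stage of the trio exome pipeline.

The pipeline operates on normalized biallelic variant records (one alternate
allele per record; multi-allelic sites are split upstream), a simple trio
pedigree (proband + father + mother, optional unaffected siblings), and an
annotation bundle per variant carrying the evidence the prioritization
filters consume: region class, HGVS-style change strings, per-database minor
allele frequencies, deleteriousness predictions, and autism-database flags.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Sex",
    "Role",
    "Region",
    "Effect",
    "Prediction",
    "InheritanceModel",
    "Individual",
    "TrioPedigree",
    "GenotypeCall",
    "VariantRecord",
    "AnnotationBundle",
    "FilterConfig",
    "InheritanceCall",
    "PrioritizedVariant",
    "variant_key",
    "HG19_PAR_X",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Role(str, enum.Enum):
    PROBAND = "proband"
    FATHER = "father"
    MOTHER = "mother"
    SIBLING = "sibling"


class Region(str, enum.Enum):
    EXONIC = "exonic"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    UTR = "UTR"
    INTERGENIC = "intergenic"
    OTHER = "other"


class Effect(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    INFRAME_DELETION = "inframe_deletion"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Prediction(str, enum.Enum):
    DELETERIOUS = "deleterious"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class InheritanceModel(str, enum.Enum):
    DE_NOVO = "de_novo"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    X_LINKED = "x_linked"
    UNCLASSIFIED = "unclassified"


#: hg19 pseudoautosomal intervals on chrX, half-open 0-based (start, end).
#: Male X genotypes inside these intervals behave autosomally; outside them
#: male calls are coerced to hemizygous.
HG19_PAR_X: tuple[tuple[int, int], ...] = ((60000, 2699520), (154931043, 155260560))


@dataclass(frozen=True)
class Individual:
    """One pedigree member."""

    id: str
    sex: Sex
    role: Role
    affected: bool = False

    def __post_init__(self) -> None:
        if self.role is Role.FATHER and self.sex is not Sex.MALE:
            raise ValueError(f"father {self.id!r} must be male")
        if self.role is Role.MOTHER and self.sex is not Sex.FEMALE:
            raise ValueError(f"mother {self.id!r} must be female")


@dataclass(frozen=True)
class TrioPedigree:
    """Proband plus both parents, with optional (unaffected) siblings."""

    family_id: str
    proband: Individual
    father: Individual
    mother: Individual
    siblings: tuple[Individual, ...] = ()

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate individual ids in family {self.family_id!r}")
        for sib in self.siblings:
            if sib.id in (self.father.id, self.mother.id):
                raise ValueError(f"sibling id {sib.id!r} collides with a parent id")
        if self.proband.role is not Role.PROBAND:
            raise ValueError("proband member must carry the proband role")

    @property
    def members(self) -> tuple[Individual, ...]:
        return (self.proband, self.father, self.mother, *self.siblings)

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.id == individual_id:
                return m
        raise KeyError(individual_id)


@dataclass(frozen=True)
class GenotypeCall:
    """Allele indices for one individual at one biallelic site.

    ``alleles`` holds 0 (ref) / 1 (alt) indices: two entries for a diploid
    call, one for a hemizygous call (male sex chromosomes outside the PAR),
    and none for a missing call.
    """

    alleles: tuple[int, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.alleles:
            raise ValueError("missing calls carry no alleles")
        if not self.missing and len(self.alleles) not in (1, 2):
            raise ValueError("non-missing calls carry one or two alleles")
        if any(a not in (0, 1) for a in self.alleles):
            raise ValueError("allele indices must be 0 (ref) or 1 (alt)")

    @property
    def hemizygous(self) -> bool:
        return len(self.alleles) == 1

    @property
    def alt_count(self) -> int:
        """Number of alternate allele copies (0..2); missing counts 0."""
        return sum(self.alleles)

    @property
    def dosage(self) -> int:
        """Alt dosage on a diploid scale: hemizygous alt counts 2, ref 0."""
        if self.missing:
            return 0
        if self.hemizygous:
            return 2 * self.alleles[0]
        return sum(self.alleles)

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and sum(self.alleles) == 1

    @property
    def is_hom_alt(self) -> bool:
        return len(self.alleles) == 2 and sum(self.alleles) == 2

    @property
    def is_hom_ref(self) -> bool:
        return len(self.alleles) == 2 and sum(self.alleles) == 0

    @property
    def has_alt(self) -> bool:
        return any(a == 1 for a in self.alleles)


# Convenient canonical calls.
HOM_REF = GenotypeCall((0, 0))
HET = GenotypeCall((0, 1))
HOM_ALT = GenotypeCall((1, 1))
HEMI_REF = GenotypeCall((0,))
HEMI_ALT = GenotypeCall((1,))
MISSING = GenotypeCall((), missing=True)


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic site with per-individual genotype calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if "," in self.alt:
            raise ValueError("records are biallelic; split multi-allelic sites first")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_x(self) -> bool:
        return self.chrom.removeprefix("chr") == "X"

    @property
    def is_y(self) -> bool:
        return self.chrom.removeprefix("chr") == "Y"

    def genotype(self, individual_id: str) -> GenotypeCall:
        return self.genotypes.get(individual_id, MISSING)

    def with_genotype(self, individual_id: str, call: GenotypeCall) -> "VariantRecord":
        gts = dict(self.genotypes)
        gts[individual_id] = call
        return replace(self, genotypes=gts)


def variant_key(v: "VariantRecord | tuple[str, int, str, str]") -> tuple[str, int, str, str]:
    if isinstance(v, VariantRecord):
        return v.key
    return tuple(v)  # type: ignore[return-value]


def in_par(chrom: str, pos: int, par_regions: tuple[tuple[int, int], ...] = HG19_PAR_X) -> bool:
    """Whether a 1-based X/Y position falls inside a pseudoautosomal interval."""
    zero = pos - 1
    return any(start <= zero < end for start, end in par_regions)


@dataclass
class AnnotationBundle:
    """Annotation evidence for one normalized variant.

    MAF absence means "not observed in that database" and is distinct from a
    recorded frequency of zero; both pass the rarity filter.
    """

    gene: str
    region: Region = Region.EXONIC
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    effect: Effect = Effect.OTHER
    maf: dict[str, float] = field(default_factory=dict)
    dbsnp_id: Optional[str] = None
    predictions: dict[str, Prediction] = field(default_factory=dict)
    cadd_scaled: Optional[float] = None
    sfari: bool = False
    autismkb: bool = False
    reported_asd_literature: bool = False
    reported_other_neuro: bool = False
    functional_category: Optional[str] = None
    roh_overlap: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        for source, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"MAF for {source!r} outside [0,1]: {f}")
        if self.cadd_scaled is not None and self.cadd_scaled < 0:
            raise ValueError("scaled CADD must be >= 0")
        exonic_only = {Effect.MISSENSE, Effect.NONSENSE, Effect.FRAMESHIFT}
        if self.effect in exonic_only and self.region not in (Region.EXONIC,):
            raise ValueError(f"effect {self.effect.value} requires an exonic region")

    @property
    def known_asd(self) -> bool:
        return self.sfari or self.autismkb or self.reported_asd_literature

    @property
    def novel(self) -> bool:
        """No dbSNP identifier → never previously reported."""
        return self.dbsnp_id is None


@dataclass
class FilterConfig:
    """Every threshold and mode switch of the pipeline.

    Defaults reproduce the published analysis: rarity at MAF >= 1% in any
    panel, at least one deleterious vote (a scaled CADD >= 15 counts as one
    vote), exonic/splice-site regions only with synonymous changes dropped,
    the dominant model applied only as a fallback, and carrier-permissive
    handling of heterozygous X-linked calls in female probands.
    """

    maf_threshold: float = 0.01
    min_deleterious_tools: int = 1
    cadd_cutoff: float = 15.0
    region_whitelist: frozenset[Region] = frozenset({Region.EXONIC, Region.SPLICE_SITE})
    drop_synonymous: bool = True
    ad_fallback: bool = True
    female_x_mode: str = "carrier_permissive"  # or "strict_homozygous"
    par_regions: tuple[tuple[int, int], ...] = HG19_PAR_X
    sharedhom_maf_floor: float = 0.01
    sharedhom_mean: float = 123.0
    sharedhom_sd: float = 25.0
    sharedhom_k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0):
            raise ValueError("maf_threshold must lie in (0, 1)")
        if self.min_deleterious_tools < 1:
            raise ValueError("min_deleterious_tools must be >= 1")
        if self.sharedhom_sd <= 0:
            raise ValueError("sharedhom_sd must be positive")
        if self.female_x_mode not in ("carrier_permissive", "strict_homozygous"):
            raise ValueError(f"unknown female_x_mode {self.female_x_mode!r}")
        if isinstance(self.region_whitelist, (set, list, tuple)):
            self.region_whitelist = frozenset(Region(r) for r in self.region_whitelist)

    @property
    def sharedhom_threshold(self) -> float:
        return self.sharedhom_mean + self.sharedhom_k * self.sharedhom_sd


@dataclass
class InheritanceCall:
    """The model assigned to one variant in one trio."""

    model: InheritanceModel
    transmitting_parent: Optional[str] = None  # "father" | "mother" | "both"
    compound_het_partner: Optional[tuple[str, int, str, str]] = None
    mendelian_consistent: bool = True

    def __post_init__(self) -> None:
        if self.model is InheritanceModel.DE_NOVO and self.transmitting_parent is not None:
            raise ValueError("de novo calls have no transmitting parent")
        if (
            self.model is InheritanceModel.AUTOSOMAL_RECESSIVE
            and self.compound_het_partner is None
            and self.transmitting_parent != "both"
        ):
            raise ValueError("non-compound recessive calls are transmitted by both parents")


@dataclass
class PrioritizedVariant:
    """A variant with its inheritance call, annotation and filter audit trail."""

    variant: VariantRecord
    call: InheritanceCall
    annotation: Optional[AnnotationBundle]
    trio_id: str
    filter_trail: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key

    @property
    def retained(self) -> bool:
        return all(passed for _, passed, _ in self.filter_trail)

    @property
    def novel(self) -> bool:
        return self.annotation is None or self.annotation.novel
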