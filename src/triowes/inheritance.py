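"""Assign trio variants to inheritance models.

Four models, evaluated per variant against the parental genotypes:

* **de novo** — the alternate allele is present in the proband and absent
  from both parents (any chromosome);
* **X-linked** — a chrX (non-PAR) alternate inherited from a carrier
  parent: hemizygous in a male proband, homozygous in a female proband, or
  (in the default carrier-permissive mode) heterozygous in a female proband
  with at least one carrier parent;
* **autosomal recessive** — proband homozygous-alternate with both parents
  heterozygous, or a compound-heterozygous pair: two heterozygous proband
  variants in one gene, one contributed by each parent;
* **autosomal dominant** — proband heterozygous with exactly one
  heterozygous parent and the other parent homozygous-reference.  The
  dominant model is a fallback: it is applied only when the other three
  models yield no candidate surviving prioritization for the trio.

Precedence is de novo > X-linked > recessive > dominant.  Genotype
configurations impossible under Mendelian transmission (and not explained
by a single new allele) are flagged via ``mendelian_consistent`` rather
than silently dropped.  Sibling genotypes never influence the model; they
serve only as post-hoc segregation annotation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Callable, Iterable, Optional

from .model import (
    AnnotationBundle,
    FilterConfig,
    GenotypeCall,
    InheritanceCall,
    InheritanceModel,
    Sex,
    TrioPedigree,
    VariantRecord,
    in_par,
)

__all__ = ["classify_variant", "find_compound_hets", "run_trio_models"]


def _mendelian_consistent_autosomal(p: int, f: int, m: int) -> bool:
    """Diploid autosomal consistency over alt dosages 0/1/2.

    A single de novo allele (proband dosage 1, both parents 0) counts as
    consistent: it is the expected signature of the de novo model, not a
    genotyping artifact.
    """
    if (p, f, m) == (1, 0, 0):
        return True
    # proband must be able to draw one allele from each parent
    for from_f in (0, 1) if f == 1 else ((0,) if f == 0 else (1,)):
        for from_m in (0, 1) if m == 1 else ((0,) if m == 0 else (1,)):
            if from_f + from_m == p:
                return True
    return False


def _x_non_par(v: VariantRecord, cfg: FilterConfig) -> bool:
    return v.is_x and not in_par(v.chrom, v.pos, cfg.par_regions)


def classify_variant(
    v: VariantRecord, trio: TrioPedigree, cfg: Optional[FilterConfig] = None
) -> InheritanceCall:
    """Classify one variant under the four inheritance models.

    Missing genotypes in the proband or either parent yield ``unclassified``.
    Compound heterozygosity needs per-gene context and is handled by
    :func:`find_compound_hets`.
    """
    cfg = cfg or FilterConfig()
    gp = v.genotype(trio.proband.id)
    gf = v.genotype(trio.father.id)
    gm = v.genotype(trio.mother.id)
    if gp.missing or gf.missing or gm.missing:
        return InheritanceCall(InheritanceModel.UNCLASSIFIED)

    male_proband = trio.proband.sex is Sex.MALE
    on_x = _x_non_par(v, cfg)

    # 1. de novo: alt present uniquely in the proband.
    if gp.has_alt and not gf.has_alt and not gm.has_alt:
        if on_x:
            consistent = True  # single new allele on the maternal X (or one of two)
        else:
            consistent = gp.alt_count == 1
        return InheritanceCall(InheritanceModel.DE_NOVO, mendelian_consistent=consistent)

    # 2. X-linked inherited (non-PAR chrX only).
    if on_x:
        return _classify_x(gp, gf, gm, male_proband, cfg)

    # 3/4. autosomal models on diploid dosages.
    p, f, m = gp.alt_count, gf.alt_count, gm.alt_count
    consistent = _mendelian_consistent_autosomal(p, f, m)
    if p == 2 and f == 1 and m == 1:
        return InheritanceCall(
            InheritanceModel.AUTOSOMAL_RECESSIVE,
            transmitting_parent="both",
            mendelian_consistent=consistent,
        )
    if p == 1:
        if f == 1 and m == 0:
            return InheritanceCall(
                InheritanceModel.AUTOSOMAL_DOMINANT,
                transmitting_parent="father",
                mendelian_consistent=consistent,
            )
        if f == 0 and m == 1:
            return InheritanceCall(
                InheritanceModel.AUTOSOMAL_DOMINANT,
                transmitting_parent="mother",
                mendelian_consistent=consistent,
            )
    return InheritanceCall(InheritanceModel.UNCLASSIFIED, mendelian_consistent=consistent)


def _classify_x(
    gp: GenotypeCall,
    gf: GenotypeCall,
    gm: GenotypeCall,
    male_proband: bool,
    cfg: FilterConfig,
) -> InheritanceCall:
    """Inherited chrX logic once the de novo rule has not fired."""
    father_alt = gf.has_alt
    mother_alt = gm.has_alt

    if male_proband:
        # Son's X comes from the mother; the father's allele is irrelevant
        # for transmission but relevant to the de novo rule (handled above).
        if gp.has_alt:
            if mother_alt:
                return InheritanceCall(InheritanceModel.X_LINKED, transmitting_parent="mother")
            # alt on the son's X not carried by the mother and not de novo
            # (the father carries it): unexplained by transmission.
            return InheritanceCall(InheritanceModel.UNCLASSIFIED, mendelian_consistent=False)
        consistent = gm.alt_count < 2
        return InheritanceCall(InheritanceModel.UNCLASSIFIED, mendelian_consistent=consistent)

    # Female proband: X from each parent.
    if gp.is_hom_alt:
        consistent = father_alt and mother_alt
        if consistent:
            return InheritanceCall(InheritanceModel.X_LINKED, transmitting_parent="both")
        return InheritanceCall(InheritanceModel.UNCLASSIFIED, mendelian_consistent=False)
    if gp.is_het:
        consistent = father_alt or mother_alt or gm.alt_count < 2
        if cfg.female_x_mode == "carrier_permissive" and (father_alt or mother_alt):
            if father_alt and not mother_alt:
                parent = "father"
            elif mother_alt and not father_alt:
                parent = "mother"
            else:
                parent = None  # ambiguous origin
            return InheritanceCall(InheritanceModel.X_LINKED, transmitting_parent=parent)
        return InheritanceCall(InheritanceModel.UNCLASSIFIED, mendelian_consistent=consistent)
    # homozygous reference
    consistent = not (gf.has_alt and gm.alt_count == 2)
    return InheritanceCall(InheritanceModel.UNCLASSIFIED, mendelian_consistent=consistent)


def find_compound_hets(
    variants: Iterable[VariantRecord],
    trio: TrioPedigree,
    annotations: dict[tuple[str, int, str, str], AnnotationBundle],
    cfg: Optional[FilterConfig] = None,
) -> dict[tuple[str, int, str, str], InheritanceCall]:
    """Detect compound-heterozygous pairs within genes.

    Two heterozygous proband variants in the same gene, one carried by the
    father only and one by the mother only, are both recessive candidates
    with mutual partner links.  All father-side × mother-side combinations
    are reported.  Variants where both parents carry the allele cannot be
    phased and are never paired.
    """
    cfg = cfg or FilterConfig()
    by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None or _x_non_par(v, cfg):
            continue
        by_gene[ann.gene].append(v)

    out: dict[tuple[str, int, str, str], InheritanceCall] = {}
    for gene_variants in by_gene.values():
        father_side: list[VariantRecord] = []
        mother_side: list[VariantRecord] = []
        for v in gene_variants:
            gp = v.genotype(trio.proband.id)
            gf = v.genotype(trio.father.id)
            gm = v.genotype(trio.mother.id)
            if not gp.is_het:
                continue
            if gf.has_alt and not gm.has_alt:
                father_side.append(v)
            elif gm.has_alt and not gf.has_alt:
                mother_side.append(v)
        for vf in father_side:
            for vm in mother_side:
                out[vf.key] = InheritanceCall(
                    InheritanceModel.AUTOSOMAL_RECESSIVE,
                    transmitting_parent="father",
                    compound_het_partner=vm.key,
                )
                out[vm.key] = InheritanceCall(
                    InheritanceModel.AUTOSOMAL_RECESSIVE,
                    transmitting_parent="mother",
                    compound_het_partner=vf.key,
                )
    return out


MAIN_MODELS = (
    InheritanceModel.DE_NOVO,
    InheritanceModel.AUTOSOMAL_RECESSIVE,
    InheritanceModel.X_LINKED,
)


def run_trio_models(
    variants: list[VariantRecord],
    trio: TrioPedigree,
    annotations: dict[tuple[str, int, str, str], AnnotationBundle],
    cfg: Optional[FilterConfig] = None,
    survivor: Optional[Callable[[VariantRecord, InheritanceCall], bool]] = None,
) -> dict[InheritanceModel, list[tuple[VariantRecord, InheritanceCall]]]:
    """Group a trio's variants into model-specific subsets.

    The three main models (de novo, recessive including compound
    heterozygosity, X-linked) are always evaluated.  The dominant model is
    the fallback: evaluated only when ``cfg.ad_fallback`` and no main-model
    candidate survives ``survivor`` (the downstream prioritization
    predicate; defaults to accepting every call).  Model subsets are
    disjoint and each variant appears exactly once across the returned
    groups plus the unclassified group.
    """
    cfg = cfg or FilterConfig()
    survivor = survivor or (lambda v, c: True)
    compound = find_compound_hets(variants, trio, annotations, cfg)

    groups: dict[InheritanceModel, list[tuple[VariantRecord, InheritanceCall]]] = {
        model: [] for model in InheritanceModel
    }
    ad_pool: list[tuple[VariantRecord, InheritanceCall]] = []
    for v in variants:
        call = classify_variant(v, trio, cfg)
        if v.key in compound and call.model in (
            InheritanceModel.UNCLASSIFIED,
            InheritanceModel.AUTOSOMAL_DOMINANT,  # each side alone looks dominant
        ):
            call = compound[v.key]
        if call.model is InheritanceModel.AUTOSOMAL_DOMINANT:
            ad_pool.append((v, call))
            continue
        groups[call.model].append((v, call))

    main_survivors = sum(
        1
        for model in MAIN_MODELS
        for (v, call) in groups[model]
        if survivor(v, call)
    )
    if cfg.ad_fallback and main_survivors == 0:
        groups[InheritanceModel.AUTOSOMAL_DOMINANT] = ad_pool
    else:
        # Dominant candidates stay unclassified when the fallback is off
        # or a main model already produced survivors.
        for v, _call in ad_pool:
            groups[InheritanceModel.UNCLASSIFIED].append(
                (v, InheritanceCall(InheritanceModel.UNCLASSIFIED))
            )
    return groups
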