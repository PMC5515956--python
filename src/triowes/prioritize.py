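"""Rare-variant prioritization: the trimming and filtering stages applied to
each trio's model-specific candidate sets.

Stage order: classify under the three main inheritance models → region trim
(coding exons and exon/intron boundaries, synonymous changes dropped) →
rarity filter (drop iff any recorded database frequency reaches the
threshold) → deleteriousness consensus (count of tools voting deleterious,
a scaled CADD above the cutoff contributing one vote) → if the trio ends up
empty and the fallback is enabled, the dominant-model candidates are pushed
through the same filters → autism-database flagging.

Every excluded variant keeps a filter trail explaining which stage removed
it and why.  dbSNP membership alone never removes a variant; it is recorded
as novelty metadata (a rule the published result requires: several retained
variants carry dbSNP ids with sub-threshold frequencies).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from .inheritance import MAIN_MODELS, run_trio_models
from .model import (
    AnnotationBundle,
    Effect,
    FilterConfig,
    InheritanceCall,
    InheritanceModel,
    PrioritizedVariant,
    Region,
    TrioPedigree,
    VariantRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "region_trim",
    "rarity_filter",
    "deleterious_consensus",
    "flag_known_genes",
    "run_pipeline",
    "run_cohort",
]


def region_trim(calls: list[PrioritizedVariant], cfg: FilterConfig) -> list[PrioritizedVariant]:
    """Keep variants in whitelisted regions; drop synonymous changes."""
    out = []
    for pv in calls:
        ann = pv.annotation
        if ann is None:
            pv.filter_trail.append(("region_trim", False, "unannotated"))
        elif ann.region not in cfg.region_whitelist:
            pv.filter_trail.append(("region_trim", False, f"region {ann.region.value}"))
        elif cfg.drop_synonymous and ann.effect is Effect.SYNONYMOUS:
            pv.filter_trail.append(("region_trim", False, "synonymous"))
        else:
            pv.filter_trail.append(("region_trim", True, ""))
            out.append(pv)
    return out


def rarity_filter(calls: list[PrioritizedVariant], cfg: FilterConfig) -> list[PrioritizedVariant]:
    """Drop a variant iff any available database frequency reaches the threshold."""
    out = []
    for pv in calls:
        ann = pv.annotation
        offending = [
            (src, f) for src, f in (ann.maf.items() if ann else ()) if f >= cfg.maf_threshold
        ]
        if offending:
            src, f = offending[0]
            pv.filter_trail.append(("rarity_filter", False, f"{src} MAF {f:g} >= {cfg.maf_threshold:g}"))
        else:
            pv.filter_trail.append(("rarity_filter", True, ""))
            out.append(pv)
    return out


def deleterious_votes(ann: AnnotationBundle, cfg: FilterConfig) -> int:
    """Number of deleteriousness votes: tools calling deleterious, plus one
    when the scaled CADD reaches the cutoff."""
    votes = sum(1 for p in ann.predictions.values() if p.value == "deleterious")
    if ann.cadd_scaled is not None and ann.cadd_scaled >= cfg.cadd_cutoff:
        votes += 1
    return votes


def deleterious_consensus(
    calls: list[PrioritizedVariant], cfg: FilterConfig
) -> list[PrioritizedVariant]:
    """Retain variants with enough deleterious votes.

    A variant with neither predictions nor a CADD score is dropped as
    unpredicted.  Splice-site variants may qualify through PredictSNP2
    alone, which the vote count naturally allows.
    """
    out = []
    for pv in calls:
        ann = pv.annotation
        if ann is None or (not ann.predictions and ann.cadd_scaled is None):
            pv.filter_trail.append(("deleterious_consensus", False, "unpredicted"))
            continue
        votes = deleterious_votes(ann, cfg)
        if votes >= cfg.min_deleterious_tools:
            pv.filter_trail.append(("deleterious_consensus", True, f"{votes} votes"))
            out.append(pv)
        else:
            pv.filter_trail.append(
                ("deleterious_consensus", False, f"{votes} votes < {cfg.min_deleterious_tools}")
            )
    return out


def flag_known_genes(
    calls: list[PrioritizedVariant],
    gene_flag_table: Optional[dict[str, dict]] = None,
) -> list[PrioritizedVariant]:
    """Attach autism-database evidence flags from a per-gene table.

    When a table is supplied its flags override whatever the annotation rows
    carried; genes absent from the table get all-false flags and a warning.
    """
    if gene_flag_table is None:
        return calls
    for pv in calls:
        ann = pv.annotation
        if ann is None:
            continue
        flags = gene_flag_table.get(ann.gene)
        if flags is None:
            log.warning("gene %s absent from evidence table; flags set false", ann.gene)
            ann.sfari = ann.autismkb = ann.reported_asd_literature = False
            continue
        ann.sfari = bool(flags.get("sfari", False))
        ann.autismkb = bool(flags.get("autismkb", False))
        ann.reported_asd_literature = bool(flags.get("reported_asd_literature", False))
        if flags.get("functional_category"):
            ann.functional_category = str(flags["functional_category"])
    return calls


def _apply_filters(
    pvs: list[PrioritizedVariant], cfg: FilterConfig
) -> tuple[list[PrioritizedVariant], list[PrioritizedVariant]]:
    """Run the three filter stages; return (survivors, all with trails)."""
    survivors = deleterious_consensus(rarity_filter(region_trim(pvs, cfg), cfg), cfg)
    return survivors, pvs


def run_pipeline(
    trio: TrioPedigree,
    variants: list[VariantRecord],
    annotations: dict[tuple[str, int, str, str], AnnotationBundle],
    cfg: Optional[FilterConfig] = None,
    gene_flag_table: Optional[dict[str, dict]] = None,
) -> list[PrioritizedVariant]:
    """End-to-end prioritization for one trio.

    Deterministic given inputs and config; an empty result is a valid
    outcome (two of the study's trios yielded no candidate genes).
    """
    cfg = cfg or FilterConfig()
    groups = run_trio_models(
        variants,
        trio,
        annotations,
        cfg,
        survivor=lambda v, call: _survives(v, annotations.get(v.key), cfg),
    )
    retained: list[PrioritizedVariant] = []
    for model in (*MAIN_MODELS, InheritanceModel.AUTOSOMAL_DOMINANT):
        pvs = [
            PrioritizedVariant(v, call, annotations.get(v.key), trio.family_id)
            for (v, call) in groups[model]
        ]
        survivors, _ = _apply_filters(pvs, cfg)
        retained.extend(survivors)
    flag_known_genes(retained, gene_flag_table)
    return retained


def _survives(
    v: VariantRecord, ann: Optional[AnnotationBundle], cfg: FilterConfig
) -> bool:
    """Whether a classified variant would pass all three filter stages."""
    if ann is None:
        return False
    if ann.region not in cfg.region_whitelist:
        return False
    if cfg.drop_synonymous and ann.effect is Effect.SYNONYMOUS:
        return False
    if any(f >= cfg.maf_threshold for f in ann.maf.values()):
        return False
    if not ann.predictions and ann.cadd_scaled is None:
        return False
    return deleterious_votes(ann, cfg) >= cfg.min_deleterious_tools


def run_cohort(
    trios: Iterable[TrioPedigree],
    variants_by_trio: dict[str, list[VariantRecord]],
    annotations: dict[tuple[str, int, str, str], AnnotationBundle],
    cfg: Optional[FilterConfig] = None,
    gene_flag_table: Optional[dict[str, dict]] = None,
) -> dict[str, list[PrioritizedVariant]]:
    """Run the per-trio pipeline over a whole cohort."""
    cfg = cfg or FilterConfig()
    return {
        trio.family_id: run_pipeline(
            trio, variants_by_trio.get(trio.family_id, []), annotations, cfg, gene_flag_table
        )
        for trio in trios
    }
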