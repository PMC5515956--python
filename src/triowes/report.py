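"""Cohort and per-trio summaries of prioritized variants.

Tallies variants by inheritance model and effect class (with integer
percentages, half-up rounding), novelty (dbSNP membership), gene-level
autism evidence, and manually curated functional categories.  Pathway
enrichment statistics are deliberately out of scope: the summary exposes
category membership counts only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .model import Effect, InheritanceModel, PrioritizedVariant, TrioPedigree

__all__ = ["CohortSummary", "summarize", "categorize_genes", "render_report", "percent_half_up"]


def percent_half_up(part: int, whole: int) -> int:
    """Integer percentage with half-up rounding (76.6 → 77, 8.5 → 9)."""
    if whole == 0:
        return 0
    ratio = Decimal(100 * part) / Decimal(whole)
    return int(ratio.quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n_trios: int = 0
    n_trios_with_findings: int = 0
    n_variants: int = 0
    n_genes: int = 0
    variants_by_model: dict[str, int] = field(default_factory=dict)
    variants_by_effect: dict[str, int] = field(default_factory=dict)
    effect_percentages: dict[str, int] = field(default_factory=dict)
    n_novel: int = 0
    n_previously_reported: int = 0
    n_probands_with_de_novo: int = 0
    genes_known_asd: int = 0
    genes_novel_candidate: int = 0
    functional_category_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSummary":
        return cls(**d)


def summarize(
    prioritized: dict[str, list[PrioritizedVariant]],
    trios: Iterable[TrioPedigree],
) -> CohortSummary:
    """Deterministic cohort tallies over per-trio prioritized variants."""
    trios = list(trios)
    summary = CohortSummary(n_trios=len(trios))
    all_pv: list[PrioritizedVariant] = []
    for trio in trios:
        pvs = prioritized.get(trio.family_id, [])
        if pvs:
            summary.n_trios_with_findings += 1
        if any(pv.call.model is InheritanceModel.DE_NOVO for pv in pvs):
            summary.n_probands_with_de_novo += 1
        all_pv.extend(pvs)

    summary.n_variants = len(all_pv)
    genes: dict[str, bool] = {}
    categories: dict[str, set[str]] = {}
    for pv in all_pv:
        model = pv.call.model.value
        summary.variants_by_model[model] = summary.variants_by_model.get(model, 0) + 1
        effect = pv.annotation.effect.value if pv.annotation else Effect.OTHER.value
        summary.variants_by_effect[effect] = summary.variants_by_effect.get(effect, 0) + 1
        if pv.novel:
            summary.n_novel += 1
        else:
            summary.n_previously_reported += 1
        if pv.annotation:
            gene = pv.annotation.gene
            genes[gene] = genes.get(gene, False) or pv.annotation.known_asd
            category = pv.annotation.functional_category or "Unknown"
            categories.setdefault(category, set()).add(gene)

    summary.n_genes = len(genes)
    summary.genes_known_asd = sum(1 for known in genes.values() if known)
    summary.genes_novel_candidate = sum(1 for known in genes.values() if not known)
    summary.effect_percentages = {
        effect: percent_half_up(count, summary.n_variants)
        for effect, count in sorted(summary.variants_by_effect.items())
    }
    summary.variants_by_model = dict(sorted(summary.variants_by_model.items()))
    summary.variants_by_effect = dict(sorted(summary.variants_by_effect.items()))
    summary.functional_category_counts = {
        cat: len(gs) for cat, gs in sorted(categories.items())
    }
    return summary


def categorize_genes(
    genes: Iterable[str], category_table: dict[str, str]
) -> dict[str, list[str]]:
    """Group genes by curated functional category; unknowns under "Unknown"."""
    out: dict[str, list[str]] = {}
    for gene in genes:
        category = category_table.get(gene) or "Unknown"
        out.setdefault(category, []).append(gene)
    return {cat: sorted(gs) for cat, gs in sorted(out.items())}


def render_report(summary: CohortSummary, fmt: str = "json") -> str:
    """Render a summary as JSON, TSV, or a human-readable text table."""
    if fmt == "json":
        return json.dumps(summary.to_dict(), indent=2, sort_keys=True)
    if fmt == "tsv":
        lines = ["field\tkey\tvalue"]
        for name, value in summary.to_dict().items():
            if isinstance(value, dict):
                for key, val in value.items():
                    lines.append(f"{name}\t{key}\t{val}")
            else:
                lines.append(f"{name}\t\t{value}")
        return "\n".join(lines) + "\n"
    if fmt == "text":
        d = summary.to_dict()
        lines = [
            f"Trios: {d['n_trios']} ({d['n_trios_with_findings']} with findings)",
            f"Variants retained: {d['n_variants']} in {d['n_genes']} genes",
            f"Novel: {d['n_novel']}  Previously reported: {d['n_previously_reported']}",
            f"Probands with de novo events: {d['n_probands_with_de_novo']}",
            f"Genes with prior ASD evidence: {d['genes_known_asd']}; novel candidates: {d['genes_novel_candidate']}",
            "By model:",
        ]
        for model, count in d["variants_by_model"].items():
            lines.append(f"  {model:22s} {count}")
        lines.append("By effect:")
        for effect, count in d["variants_by_effect"].items():
            pct = d["effect_percentages"].get(effect, 0)
            lines.append(f"  {effect:22s} {count} ({pct}%)")
        lines.append("Functional categories (genes):")
        for category, count in d["functional_category_counts"].items():
            lines.append(f"  {category}: {count}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
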