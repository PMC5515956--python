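"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (via pysam) for genotypes, 6-column PED for pedigrees, TSV for
annotation tables, and BED for interval lists (runs of homozygosity,
pseudoautosomal regions).  All records are normalized on the way in:
multi-allelic sites are split into one biallelic record per alternate
allele, and male X/Y calls outside the pseudoautosomal regions are coerced
to hemizygous regardless of how the VCF spells them.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Optional

import pandas as pd
import pysam

from .model import (
    AnnotationBundle,
    Effect,
    FilterConfig,
    GenotypeCall,
    Individual,
    MISSING,
    Prediction,
    Region,
    Role,
    Sex,
    TrioPedigree,
    VariantRecord,
    in_par,
)
from .hgvs import parse_hgvs_effect

log = logging.getLogger(__name__)

PREDICTION_TOOLS = ("polyphen2", "sift", "mutationtaster", "predictsnp2")
MAF_SOURCES = ("local", "ExAC", "1000G", "dbSNP")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _coerce_male_sex_chrom(
    alleles: tuple[int, ...], chrom: str, pos: int, cfg_par: tuple[tuple[int, int], ...]
) -> tuple[int, ...]:
    chrom_short = chrom.removeprefix("chr")
    if chrom_short not in ("X", "Y"):
        return alleles
    if chrom_short == "X" and in_par(chrom, pos, cfg_par):
        return alleles
    if len(alleles) <= 1:
        return alleles
    # Diploid spelling of a hemizygous call: any alt evidence wins.
    return (1,) if any(a == 1 for a in alleles) else (0,)


def read_trio_vcf(
    path: str | os.PathLike,
    pedigree: TrioPedigree,
    cfg: Optional[FilterConfig] = None,
) -> list[VariantRecord]:
    """Read a multi-sample VCF into normalized biallelic records.

    Multi-allelic sites are split (one record per alternate; allele indices
    other than the kept alternate count as reference so summed dosage is
    conserved) and male X/Y genotypes outside the PAR become hemizygous.
    Ordering by (chrom, pos) follows the file.  A pedigree member whose
    sample id is absent from the VCF is a fatal error; a malformed genotype
    field degrades to a missing call with a warning.
    """
    cfg = cfg or FilterConfig()
    male_ids = {m.id for m in pedigree.members if m.sex is Sex.MALE}
    records: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        for member in pedigree.members:
            if member.id not in samples:
                raise ValueError(f"sample {member.id!r} missing from VCF {path}")
        wanted = [m.id for m in pedigree.members]
        for site in vcf:
            alts = site.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: dict[str, GenotypeCall] = {}
                for sample_id in wanted:
                    try:
                        raw = site.samples[sample_id].get("GT", (None,))
                    except Exception:  # malformed genotype field
                        log.warning(
                            "malformed genotype for %s at %s:%d; treating as missing",
                            sample_id, site.chrom, site.pos,
                        )
                        genotypes[sample_id] = MISSING
                        continue
                    if raw is None or all(a is None for a in raw):
                        genotypes[sample_id] = MISSING
                        continue
                    alleles = tuple(1 if a == alt_index else 0 for a in raw if a is not None)
                    if sample_id in male_ids:
                        alleles = _coerce_male_sex_chrom(
                            alleles, site.chrom, site.pos, cfg.par_regions
                        )
                    genotypes[sample_id] = GenotypeCall(alleles)
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        genotypes=genotypes,
                        quality=site.qual,
                    )
                )
    return records


def write_vcf(
    path: str | os.PathLike,
    records: Iterable[VariantRecord],
    sample_ids: list[str],
    contigs: Optional[Iterable[str]] = None,
) -> None:
    """Write biallelic records as an uncompressed VCF 4.2 file."""
    records = list(records)
    if contigs is None:
        seen: list[str] = []
        for r in records:
            if r.chrom not in seen:
                seen.append(r.chrom)
        contigs = seen
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig in contigs:
        header.contigs.add(contig)
    for sid in sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for r in records:
            site = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt), qual=r.quality
            )
            for sid in sample_ids:
                call = r.genotype(sid)
                if call.missing:
                    site.samples[sid]["GT"] = (None,)
                else:
                    site.samples[sid]["GT"] = call.alleles
            out.write(site)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}


def read_pedigree(path: str | os.PathLike) -> TrioPedigree:
    """Parse a single-family 6-column PED file into a trio pedigree.

    Roles are inferred from the parent columns: the affected child with both
    parents present in the file is the proband, further children are
    siblings, and rows with 0/0 parent ids are the founders.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED line has fewer than 6 columns: {line!r}")
            rows.append(parts[:6])
    if not rows:
        raise ValueError(f"empty PED file: {path}")
    families = {r[0] for r in rows}
    if len(families) != 1:
        raise ValueError(f"expected one family per PED file, found {sorted(families)}")
    ids = {r[1] for r in rows}

    children = [r for r in rows if r[2] != "0" or r[3] != "0"]
    for r in children:
        if r[2] not in ids or r[3] not in ids:
            raise ValueError(f"parent of {r[1]!r} missing from PED file")
    probands = [r for r in children if r[5] == "2"]
    if len(probands) != 1:
        raise ValueError(f"expected exactly one affected child, found {len(probands)}")
    prow = probands[0]

    def sex_of(code: str) -> Sex:
        return _PED_SEX.get(code, Sex.UNKNOWN)

    by_id = {r[1]: r for r in rows}
    father_row, mother_row = by_id[prow[2]], by_id[prow[3]]
    proband = Individual(prow[1], sex_of(prow[4]), Role.PROBAND, affected=True)
    father = Individual(father_row[1], Sex.MALE, Role.FATHER)
    mother = Individual(mother_row[1], Sex.FEMALE, Role.MOTHER)
    siblings = tuple(
        Individual(r[1], sex_of(r[4]), Role.SIBLING, affected=r[5] == "2")
        for r in children
        if r[1] != prow[1]
    )
    return TrioPedigree(prow[0], proband, father, mother, siblings)


def write_pedigree(path: str | os.PathLike, trio: TrioPedigree) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for m in trio.members:
            pat = trio.father.id if m.role in (Role.PROBAND, Role.SIBLING) else "0"
            mat = trio.mother.id if m.role in (Role.PROBAND, Role.SIBLING) else "0"
            pheno = "2" if m.affected else "1"
            fh.write(
                f"{trio.family_id}\t{m.id}\t{pat}\t{mat}\t{sex_code[m.sex]}\t{pheno}\n"
            )


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.upper() in ("NA", "N/A", "."):
        return None
    return float(s)


def _row_to_bundle(row: pd.Series) -> AnnotationBundle:
    maf: dict[str, float] = {}
    for source in MAF_SOURCES:
        val = _opt_float(row.get(f"maf_{source.lower()}"))
        if val is not None:
            maf[source] = val
    predictions: dict[str, Prediction] = {}
    for tool in PREDICTION_TOOLS:
        raw = row.get(tool)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() in ("", "NA", "."):
            continue
        predictions[tool] = Prediction(str(raw).strip().lower())
    cdna = row.get("cdna_change")
    prot = row.get("protein_change")
    cdna = None if (cdna is None or (isinstance(cdna, float) and math.isnan(cdna)) or str(cdna).strip() in ("", "NA")) else str(cdna)
    prot = None if (prot is None or (isinstance(prot, float) and math.isnan(prot)) or str(prot).strip() in ("", "NA", "_")) else str(prot)
    region = Region(str(row.get("region", "exonic")))
    if cdna or prot:
        effect = parse_hgvs_effect(cdna, prot)
    else:
        effect = Effect.SPLICE_SITE if region is Region.SPLICE_SITE else Effect.OTHER
    dbsnp = row.get("dbsnp_id")
    dbsnp = None if (dbsnp is None or (isinstance(dbsnp, float) and math.isnan(dbsnp)) or str(dbsnp).strip() in ("", "NA", ".")) else str(dbsnp)
    roh = row.get("roh")
    roh_overlap = None
    if roh is not None and not (isinstance(roh, float) and math.isnan(roh)) and str(roh).strip() not in ("", "NA"):
        chrom, span = str(roh).split(":")
        start, end = span.replace("–", "-").split("-")
        roh_overlap = (chrom, int(start), int(end))

    def flag(col: str) -> bool:
        v = row.get(col)
        return str(v).strip().lower() in ("1", "true", "yes") if v is not None else False

    return AnnotationBundle(
        gene=str(row["gene"]),
        region=region,
        cdna_change=cdna,
        protein_change=prot,
        effect=effect,
        maf=maf,
        dbsnp_id=dbsnp,
        predictions=predictions,
        cadd_scaled=_opt_float(row.get("cadd_scaled")),
        sfari=flag("sfari"),
        autismkb=flag("autismkb"),
        reported_asd_literature=flag("reported_asd_literature"),
        reported_other_neuro=flag("reported_other_neuro"),
        functional_category=row.get("functional_category") if isinstance(row.get("functional_category"), str) else None,
        roh_overlap=roh_overlap,
    )


def read_annotations(path: str | os.PathLike) -> dict[tuple[str, int, str, str], AnnotationBundle]:
    """Read a per-variant annotation TSV keyed by (chrom, pos, ref, alt).

    Empty MAF cells mean "not observed in that database" and are omitted
    from the MAF map rather than recorded as zero.  Duplicate keys and MAFs
    outside [0, 1] are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    out: dict[tuple[str, int, str, str], AnnotationBundle] = {}
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        if key in out:
            raise ValueError(f"duplicate annotation key {key}")
        out[key] = _row_to_bundle(row)
    return out


def write_annotations(
    path: str | os.PathLike,
    annotations: dict[tuple[str, int, str, str], AnnotationBundle],
) -> None:
    rows = []
    for (chrom, pos, ref, alt), ann in annotations.items():
        row: dict[str, object] = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": ann.gene,
            "region": ann.region.value,
            "cdna_change": ann.cdna_change or "",
            "protein_change": ann.protein_change or "",
            "dbsnp_id": ann.dbsnp_id or "",
            "cadd_scaled": "" if ann.cadd_scaled is None else ann.cadd_scaled,
            "sfari": int(ann.sfari),
            "autismkb": int(ann.autismkb),
            "reported_asd_literature": int(ann.reported_asd_literature),
            "reported_other_neuro": int(ann.reported_other_neuro),
            "functional_category": ann.functional_category or "",
            "roh": "" if ann.roh_overlap is None else f"{ann.roh_overlap[0]}:{ann.roh_overlap[1]}-{ann.roh_overlap[2]}",
        }
        for source in MAF_SOURCES:
            row[f"maf_{source.lower()}"] = (
                "" if source not in ann.maf else repr(ann.maf[source])
            )
        for tool in PREDICTION_TOOLS:
            row[tool] = ann.predictions.get(tool, Prediction.UNKNOWN).value if ann.predictions.get(tool) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read half-open 0-based BED intervals (chrom, start, end)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.append((chrom, int(start), int(end)))
    return out
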