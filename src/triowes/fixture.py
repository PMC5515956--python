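"""Packaged fixture of the study's printed per-trio results.

The raw exomes behind the published cohort were never deposited, so the
cohort is reproducible only through its printed tables.  This module ships
them as TSVs and loads them into the pipeline's native objects:

* ``study_trios.tsv`` — the 19 trios (proband sex, sibling if sequenced,
  consanguinity flag), two of which yielded no candidate genes;
* ``study_variants.tsv`` — the 47 validated rare variants with per-member
  genotype states, printed inheritance mode, scaled CADD, per-database
  frequencies, dbSNP ids and run-of-homozygosity intervals;
* ``study_genes.tsv`` — per-gene evidence flags (SFARI, AutismKB, ASD
  literature, other neurological disorders) and the manually curated
  functional category.

Genomic coordinates are NOT printed in the source tables; the fixture's
positions are synthetic keys placed on each gene's true chromosome (inside
the printed ROH interval where one exists, outside the hg19 PARs for chrX
genes).  Rows whose printed genotypes conflict with their stated model
carry a per-row provenance note.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Optional

import pandas as pd

from .formats import _row_to_bundle
from .model import (
    AnnotationBundle,
    GenotypeCall,
    Individual,
    Role,
    Sex,
    TrioPedigree,
    VariantRecord,
)

#: SHA-256 digests of the packaged fixture files; a mismatch means the
#: install is corrupted and loading aborts.
FIXTURE_SHA256 = {
    "study_trios.tsv": "4763f4cbe4a8eef8dba26069e206bc3aec22cda722cd846d5bb54dda7b9cd7f6",
    "study_variants.tsv": "71a4f3a45ac05530976b45a634cc55549b6f06cc8f3c21aaa41926c5e7f87bd1",
    "study_genes.tsv": "26bb01a22d4a6da04472029caf7eb5afca19f598ad7a19913975bacdaec118af",
}

_GT = {
    "het": GenotypeCall((0, 1)),
    "hom_ref": GenotypeCall((0, 0)),
    "hom_alt": GenotypeCall((1, 1)),
    "hemi_ref": GenotypeCall((0,)),
    "hemi_alt": GenotypeCall((1,)),
}


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("triowes.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = FIXTURE_SHA256[name]
    if not expected.startswith("PLACEHOLDER") and digest != expected:
        raise RuntimeError(f"fixture file {name} checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype=str, keep_default_na=False)


def member_ids(trio_id: str) -> dict[str, str]:
    return {
        "proband": f"{trio_id}-P",
        "father": f"{trio_id}-F",
        "mother": f"{trio_id}-M",
        "sibling": f"{trio_id}-S",
    }


def load_study_fixture() -> tuple[
    list[TrioPedigree],
    dict[str, list[VariantRecord]],
    dict[tuple[str, int, str, str], AnnotationBundle],
]:
    """Load the packaged study fixture.

    Returns the 19 trios, a per-trio map of variant records (empty lists for
    the two trios without candidate genes), and the annotation map keyed by
    (chrom, pos, ref, alt) with gene-evidence flags attached.
    """
    trios_df = _read_packaged("study_trios.tsv")
    variants_df = _read_packaged("study_variants.tsv")
    genes_df = _read_packaged("study_genes.tsv")

    gene_rows = {r["gene"]: r for _, r in genes_df.iterrows()}

    trios: list[TrioPedigree] = []
    variants: dict[str, list[VariantRecord]] = {}
    for _, row in trios_df.iterrows():
        tid = row["trio_id"]
        ids = member_ids(tid)
        siblings: tuple[Individual, ...] = ()
        if row["sibling_sex"]:
            siblings = (
                Individual(ids["sibling"], Sex(row["sibling_sex"]), Role.SIBLING),
            )
        trios.append(
            TrioPedigree(
                family_id=tid,
                proband=Individual(ids["proband"], Sex(row["proband_sex"]), Role.PROBAND, affected=True),
                father=Individual(ids["father"], Sex.MALE, Role.FATHER),
                mother=Individual(ids["mother"], Sex.FEMALE, Role.MOTHER),
                siblings=siblings,
            )
        )
        variants[tid] = []

    annotations: dict[tuple[str, int, str, str], AnnotationBundle] = {}
    for _, row in variants_df.iterrows():
        tid = row["trio_id"]
        ids = member_ids(tid)
        genotypes = {
            ids["proband"]: _GT[row["gt_proband"]],
            ids["father"]: _GT[row["gt_father"]],
            ids["mother"]: _GT[row["gt_mother"]],
        }
        if row["gt_sibling"]:
            genotypes[ids["sibling"]] = _GT[row["gt_sibling"]]
        record = VariantRecord(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            genotypes=genotypes,
        )
        variants[tid].append(record)

        bundle = _row_to_bundle(row.replace("", None))
        flags = gene_rows.get(row["gene"])
        if flags is not None:
            bundle.sfari = flags["sfari"] == "1"
            bundle.autismkb = flags["autismkb"] == "1"
            bundle.reported_asd_literature = flags["reported_asd_literature"] == "1"
            bundle.reported_other_neuro = flags["reported_other_neuro"] == "1"
            bundle.functional_category = flags["functional_category"]
        if record.key in annotations:
            raise ValueError(f"duplicate fixture variant key {record.key}")
        annotations[record.key] = bundle

    return trios, variants, annotations


def printed_modes() -> dict[tuple[str, int, str, str], str]:
    """Map of variant key → inheritance mode exactly as printed."""
    df = _read_packaged("study_variants.tsv")
    return {
        (r["chrom"], int(r["pos"]), r["ref"], r["alt"]): r["mode"]
        for _, r in df.iterrows()
    }


def gene_flag_table() -> dict[str, dict[str, bool | str]]:
    """Per-gene autism-evidence flags and functional category."""
    df = _read_packaged("study_genes.tsv")
    out: dict[str, dict[str, bool | str]] = {}
    for _, r in df.iterrows():
        out[r["gene"]] = {
            "sfari": r["sfari"] == "1",
            "autismkb": r["autismkb"] == "1",
            "reported_asd_literature": r["reported_asd_literature"] == "1",
            "reported_other_neuro": r["reported_other_neuro"] == "1",
            "functional_category": r["functional_category"],
        }
    return out
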