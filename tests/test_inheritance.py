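"""Inheritance-model classification against the hand-enumerated truth table,
compound-heterozygote pairing, and the dominant-model fallback."""

import csv
from itertools import combinations
from pathlib import Path

import pytest

from triowes.inheritance import classify_variant, find_compound_hets, run_trio_models
from triowes.model import (
    AnnotationBundle,
    FilterConfig,
    GenotypeCall,
    Individual,
    InheritanceModel,
    Role,
    Sex,
    TrioPedigree,
    VariantRecord,
)

TRUTH = Path(__file__).parent / "data" / "classification_truth.tsv"

HET = GenotypeCall((0, 1))
HOM_REF = GenotypeCall((0, 0))
HOM_ALT = GenotypeCall((1, 1))
HEMI_REF = GenotypeCall((0,))
HEMI_ALT = GenotypeCall((1,))
DIPLOID = {0: HOM_REF, 1: HET, 2: HOM_ALT}
HEMI = {0: HEMI_REF, 1: HEMI_ALT}


def make_trio(proband_sex=Sex.MALE):
    return TrioPedigree(
        "FAM",
        Individual("P", proband_sex, Role.PROBAND, affected=True),
        Individual("F", Sex.MALE, Role.FATHER),
        Individual("M", Sex.FEMALE, Role.MOTHER),
    )


def make_variant(chrom, gp, gf, gm, pos=1_000_000):
    return VariantRecord(chrom, pos, "A", "G", {"P": gp, "F": gf, "M": gm})


def _truth_rows():
    with open(TRUTH) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        return list(reader)


@pytest.mark.parametrize(
    "row", _truth_rows(), ids=lambda r: f"{r['context']}-{r['proband']}{r['father']}{r['mother']}"
)
def test_matches_exhaustive_truth_table(row):
    """classify_variant agrees with the committed enumeration of all 27
    autosomal and 12 male-X genotype configurations."""
    if row["context"] == "autosomal":
        v = make_variant(
            "chr5",
            DIPLOID[int(row["proband"])],
            DIPLOID[int(row["father"])],
            DIPLOID[int(row["mother"])],
        )
    else:
        v = make_variant(
            "chrX",
            HEMI[int(row["proband"])],
            HEMI[int(row["father"])],
            DIPLOID[int(row["mother"])],
            pos=50_000_000,
        )
    call = classify_variant(v, make_trio())
    assert call.model.value == row["model"]
    assert (call.transmitting_parent or "") == row["transmitting_parent"]
    assert call.mendelian_consistent == (row["consistent"] == "1")


def test_missing_genotype_is_unclassified():
    v = VariantRecord("chr5", 100, "A", "G", {"P": GenotypeCall((), missing=True),
                                              "F": HOM_REF, "M": HOM_REF})
    assert classify_variant(v, make_trio()).model is InheritanceModel.UNCLASSIFIED


def test_parent_swap_symmetry():
    """Swapping parental genotypes preserves de novo / recessive calls and
    flips the transmitting parent of dominant calls."""
    trio = make_trio()
    for gp in (HET, HOM_ALT):
        for gf_dosage in range(3):
            for gm_dosage in range(3):
                v = make_variant("chr5", gp, DIPLOID[gf_dosage], DIPLOID[gm_dosage])
                w = make_variant("chr5", gp, DIPLOID[gm_dosage], DIPLOID[gf_dosage])
                a, b = classify_variant(v, trio), classify_variant(w, trio)
                assert a.model is b.model
                flip = {"father": "mother", "mother": "father", "both": "both", None: None}
                assert b.transmitting_parent == flip[a.transmitting_parent]


class TestFemaleX:
    def test_het_with_carrier_father_is_x_linked_when_permissive(self):
        trio = make_trio(Sex.FEMALE)
        v = make_variant("chrX", HET, HEMI_ALT, HOM_REF, pos=50_000_000)
        call = classify_variant(v, trio, FilterConfig(female_x_mode="carrier_permissive"))
        assert call.model is InheritanceModel.X_LINKED
        assert call.transmitting_parent == "father"

    def test_het_unclassified_when_strict(self):
        trio = make_trio(Sex.FEMALE)
        v = make_variant("chrX", HET, HEMI_ALT, HOM_REF, pos=50_000_000)
        call = classify_variant(v, trio, FilterConfig(female_x_mode="strict_homozygous"))
        assert call.model is InheritanceModel.UNCLASSIFIED

    def test_homozygous_requires_both_parents(self):
        trio = make_trio(Sex.FEMALE)
        v = make_variant("chrX", HOM_ALT, HEMI_ALT, HET, pos=50_000_000)
        call = classify_variant(v, trio, FilterConfig(female_x_mode="strict_homozygous"))
        assert call.model is InheritanceModel.X_LINKED
        assert call.transmitting_parent == "both"
        bad = make_variant("chrX", HOM_ALT, HEMI_REF, HET, pos=50_000_000)
        call = classify_variant(bad, trio)
        assert call.model is InheritanceModel.UNCLASSIFIED
        assert not call.mendelian_consistent

    def test_de_novo_precedes_x_linked(self):
        trio = make_trio(Sex.FEMALE)
        v = make_variant("chrX", HET, HEMI_REF, HOM_REF, pos=50_000_000)
        assert classify_variant(v, trio).model is InheritanceModel.DE_NOVO


def _ann(gene):
    return AnnotationBundle(gene=gene)


class TestCompoundHets:
    def test_one_from_each_parent_pairs(self):
        trio = make_trio()
        v1 = make_variant("chr5", HET, HET, HOM_REF, pos=100)
        v2 = make_variant("chr5", HET, HOM_REF, HET, pos=200)
        anns = {v1.key: _ann("G1"), v2.key: _ann("G1")}
        calls = find_compound_hets([v1, v2], trio, anns)
        assert calls[v1.key].model is InheritanceModel.AUTOSOMAL_RECESSIVE
        assert calls[v1.key].compound_het_partner == v2.key
        assert calls[v2.key].compound_het_partner == v1.key

    def test_same_parent_both_sites_no_pair(self):
        trio = make_trio()
        v1 = make_variant("chr5", HET, HOM_REF, HET, pos=100)
        v2 = make_variant("chr5", HET, HOM_REF, HET, pos=200)
        anns = {v1.key: _ann("G1"), v2.key: _ann("G1")}
        assert find_compound_hets([v1, v2], trio, anns) == {}

    def test_different_genes_no_pair(self):
        trio = make_trio()
        v1 = make_variant("chr5", HET, HET, HOM_REF, pos=100)
        v2 = make_variant("chr5", HET, HOM_REF, HET, pos=200)
        anns = {v1.key: _ann("G1"), v2.key: _ann("G2")}
        assert find_compound_hets([v1, v2], trio, anns) == {}

    def test_all_cross_parent_combinations_reported(self):
        """Three qualifying variants (father-side {v1}, mother-side {v2,v3})
        must produce the same pairs as brute-force enumeration."""
        trio = make_trio()
        v1 = make_variant("chr5", HET, HET, HOM_REF, pos=100)
        v2 = make_variant("chr5", HET, HOM_REF, HET, pos=200)
        v3 = make_variant("chr5", HET, HOM_REF, HET, pos=300)
        variants = [v1, v2, v3]
        anns = {v.key: _ann("G1") for v in variants}

        # independent brute-force oracle over all unordered pairs
        def carrier_side(v):
            gf, gm = v.genotype("F"), v.genotype("M")
            if gf.has_alt and not gm.has_alt:
                return "father"
            if gm.has_alt and not gf.has_alt:
                return "mother"
            return None

        expected_pairs = {
            frozenset((a.key, b.key))
            for a, b in combinations(variants, 2)
            if a.genotype("P").is_het and b.genotype("P").is_het
            and carrier_side(a) and carrier_side(b)
            and carrier_side(a) != carrier_side(b)
        }
        calls = find_compound_hets(variants, trio, anns)
        got_pairs = {
            frozenset((k, c.compound_het_partner)) for k, c in calls.items()
        }
        assert got_pairs == expected_pairs == {frozenset((v1.key, v2.key)),
                                               frozenset((v1.key, v3.key))}


class TestAdFallback:
    def _annotated(self, *variants, gene="G"):
        return {
            v.key: AnnotationBundle(gene=f"{gene}{i}", cadd_scaled=30.0)
            for i, v in enumerate(variants)
        }

    def test_ad_applied_when_main_models_empty(self):
        trio = make_trio()
        v = make_variant("chr5", HET, HET, HOM_REF)
        groups = run_trio_models([v], trio, self._annotated(v))
        assert [x[0] for x in groups[InheritanceModel.AUTOSOMAL_DOMINANT]] == [v]

    def test_ad_suppressed_by_surviving_main_model(self):
        trio = make_trio()
        dn = make_variant("chr5", HET, HOM_REF, HOM_REF, pos=100)
        ad = make_variant("chr5", HET, HET, HOM_REF, pos=200)
        groups = run_trio_models([dn, ad], trio, self._annotated(dn, ad))
        assert groups[InheritanceModel.AUTOSOMAL_DOMINANT] == []
        assert [x[0] for x in groups[InheritanceModel.DE_NOVO]] == [dn]

    def test_ad_applied_when_main_survivor_fails_prioritization(self):
        """The fallback is decided after prioritization: a de novo call that
        will not survive the filters does not block the dominant model."""
        trio = make_trio()
        dn = make_variant("chr5", HET, HOM_REF, HOM_REF, pos=100)
        ad = make_variant("chr5", HET, HET, HOM_REF, pos=200)
        anns = self._annotated(dn, ad)
        groups = run_trio_models(
            [dn, ad], trio, anns, survivor=lambda v, c: v.key != dn.key
        )
        assert [x[0] for x in groups[InheritanceModel.AUTOSOMAL_DOMINANT]] == [ad]

    def test_fallback_disabled(self):
        trio = make_trio()
        v = make_variant("chr5", HET, HET, HOM_REF)
        groups = run_trio_models([v], trio, self._annotated(v), FilterConfig(ad_fallback=False))
        assert groups[InheritanceModel.AUTOSOMAL_DOMINANT] == []


def test_disjoint_and_complete_grouping(study, default_cfg):
    """Each fixture variant lands in exactly one model group; group sizes
    sum to the input count."""
    trios, variants, annotations = study
    for trio in trios:
        vs = variants[trio.family_id]
        groups = run_trio_models(vs, trio, annotations, default_cfg)
        keys = [v.key for pairs in groups.values() for (v, _) in pairs]
        assert len(keys) == len(vs)
        assert len(set(keys)) == len(keys)
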