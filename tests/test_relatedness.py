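"""Relatedness estimators: closed-form single-site values, brute-force
cross-checks, invariances, and simulation calibration."""

import numpy as np
import pytest

from triowes.model import FilterConfig
from triowes.relatedness import (
    GenotypeMatrix,
    ajk_statistic,
    genotype_matrix_from_records,
    king_kinship,
    shared_homozygosity,
    verify_trio,
)
from triowes.simulate import simulate_pair, simulate_trio_matrix


def make_matrix(dosages, freqs):
    dosages = np.asarray(dosages, dtype=np.int8)
    sites = [("chr1", i + 1, "A", "G") for i in range(dosages.shape[0])]
    return GenotypeMatrix(["A", "B"], sites, dosages, np.asarray(freqs, float))


# --- independent brute-force oracles ---------------------------------------

def ajk_loop(dosages, freqs, j, k):
    terms = []
    for (xj, xk), p in zip(dosages, freqs):
        if 0 < p < 1:
            terms.append((xj - 2 * p) * (xk - 2 * p) / (2 * p * (1 - p)))
    return sum(terms) / len(terms)


def king_loop(dosages):
    het_j = sum(1 for xj, _ in dosages if xj == 1)
    het_k = sum(1 for _, xk in dosages if xk == 1)
    both = sum(1 for xj, xk in dosages if xj == 1 and xk == 1)
    opp = sum(1 for xj, xk in dosages if {xj, xk} == {0, 2})
    return (both - 2 * opp) / (het_j + het_k)


class TestAjk:
    def test_single_site_opposite_homozygotes(self):
        # p=0.5, x_j=0, x_k=2: (0-1)(2-1)/0.5 = -2
        G = make_matrix([[0, 2]], [0.5])
        assert ajk_statistic(G, "A", "B") == pytest.approx(-2.0)

    def test_single_site_double_het_is_zero(self):
        G = make_matrix([[1, 1]], [0.5])
        assert ajk_statistic(G, "A", "B") == pytest.approx(0.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(11)
        dosages = rng.integers(0, 3, size=(300, 2))
        freqs = rng.uniform(0.05, 0.95, size=300)
        G = make_matrix(dosages, freqs)
        assert ajk_statistic(G, "A", "B") == pytest.approx(
            ajk_loop(dosages, freqs, 0, 1))

    def test_monomorphic_only_is_error(self):
        G = make_matrix([[1, 1]], [0.0])
        with pytest.raises(ValueError, match="informative"):
            ajk_statistic(G, "A", "B")

    def test_duplicated_columns_approach_one(self):
        G = simulate_pair("duplicate", 8000, seed=3)
        assert ajk_statistic(G, "A", "B") == pytest.approx(1.0, abs=0.05)


class TestSharedHomozygosity:
    def test_identical_hom_alt_vectors(self, default_cfg):
        G = make_matrix([[2, 2]] * 200, [0.3] * 200)
        n, verdict = shared_homozygosity(G, "A", "B", default_cfg)
        assert n == 200
        assert verdict == "confirmed"  # 200 >= 123 + 25

    def test_no_overlap_not_confirmed(self, default_cfg):
        G = make_matrix([[2, 1]] * 50, [0.3] * 50)
        n, verdict = shared_homozygosity(G, "A", "B", default_cfg)
        assert n == 0 and verdict == "not_confirmed"

    def test_threshold_is_mean_plus_k_sd(self):
        cfg = FilterConfig()  # mu=123, sigma=25, k=1 -> 148
        G = make_matrix([[2, 2]] * 100, [0.3] * 100)
        n, verdict = shared_homozygosity(G, "A", "B", cfg)
        assert n == 100 and verdict == "not_confirmed"
        G = make_matrix([[2, 2]] * 148, [0.3] * 148)
        assert shared_homozygosity(G, "A", "B", cfg)[1] == "confirmed"

    def test_rare_sites_excluded_by_maf_floor(self, default_cfg):
        G = make_matrix([[2, 2]] * 10, [0.001] * 10)
        n, _ = shared_homozygosity(G, "A", "B", default_cfg)
        assert n == 0


class TestKing:
    def test_all_double_het_is_half(self):
        G = make_matrix([[1, 1]] * 10, [0.5] * 10)
        assert king_kinship(G, "A", "B") == pytest.approx(0.5)

    def test_opposite_homozygotes_negative(self):
        G = make_matrix([[0, 2], [2, 0], [1, 1]], [0.5] * 3)
        assert king_kinship(G, "A", "B") < 0

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, size=(500, 2))
        G = make_matrix(dosages, np.full(500, 0.3))
        assert king_kinship(G, "A", "B") == pytest.approx(king_loop(dosages))

    def test_no_heterozygous_sites_is_error(self):
        G = make_matrix([[0, 2], [2, 0]], [0.5, 0.5])
        with pytest.raises(ValueError, match="heterozygous"):
            king_kinship(G, "A", "B")


class TestInvariances:
    @pytest.mark.parametrize("stat", [ajk_statistic, king_kinship])
    def test_symmetry_under_sample_swap(self, stat):
        G = simulate_pair("parent_offspring", 2000, seed=9)
        assert stat(G, "A", "B") == pytest.approx(stat(G, "B", "A"))

    def test_shared_hom_symmetry(self, default_cfg):
        G = simulate_pair("parent_offspring", 2000, seed=9)
        assert shared_homozygosity(G, "A", "B", default_cfg) == \
            shared_homozygosity(G, "B", "A", default_cfg)

    def test_site_permutation_invariance(self, default_cfg):
        G = simulate_pair("full_sib", 1500, seed=4)
        perm = np.random.default_rng(0).permutation(1500)
        H = GenotypeMatrix(G.samples, [G.sites[i] for i in perm],
                           G.dosages[perm], G.allele_freqs[perm])
        assert ajk_statistic(H, "A", "B") == pytest.approx(ajk_statistic(G, "A", "B"))
        assert king_kinship(H, "A", "B") == pytest.approx(king_kinship(G, "A", "B"))
        assert shared_homozygosity(H, "A", "B", default_cfg)[0] == \
            shared_homozygosity(G, "A", "B", default_cfg)[0]

    def test_missing_sites_skipped_pairwise(self):
        dosages = np.array([[1, 1], [-1, 2], [1, 1]], dtype=np.int8)
        G = GenotypeMatrix(["A", "B"], [("chr1", i, "A", "G") for i in range(3)],
                           dosages, np.full(3, 0.4))
        assert king_kinship(G, "A", "B") == pytest.approx(0.5)
        assert ajk_statistic(G, "A", "B") == pytest.approx(
            ajk_loop([[1, 1], [1, 1]], [0.4, 0.4], 0, 1))


class TestCalibration:
    def test_parent_offspring_no_opposite_homozygotes(self):
        G = simulate_pair("parent_offspring", 5000, seed=2)
        xa, xb = G.dosages[:, 0], G.dosages[:, 1]
        assert not np.any(((xa == 0) & (xb == 2)) | ((xa == 2) & (xb == 0)))

    def test_unrelated_pair_means_near_zero(self):
        """Over 200 unrelated pairs, mean A_jk and mean kinship sit within
        3 standard errors of zero."""
        ajks, phis = [], []
        for s in range(200):
            G = simulate_pair("unrelated", 400, seed=s)
            ajks.append(ajk_statistic(G, "A", "B"))
            phis.append(king_kinship(G, "A", "B"))
        for vals in (ajks, phis):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals)) < 3 * se + 1e-12


class TestVerifyTrio:
    def test_true_trio_confirmed(self):
        G = simulate_trio_matrix(4000, seed=21)
        from triowes.model import Individual, Role, Sex, TrioPedigree

        trio = TrioPedigree(
            "T", Individual("P", Sex.MALE, Role.PROBAND, affected=True),
            Individual("F", Sex.MALE, Role.FATHER),
            Individual("M", Sex.FEMALE, Role.MOTHER))
        result = verify_trio(trio, G)
        assert result["parenthood_confirmed"]

    def test_swapped_proband_not_confirmed(self):
        G = simulate_trio_matrix(4000, seed=22, proband="unrelated")
        from triowes.model import Individual, Role, Sex, TrioPedigree

        trio = TrioPedigree(
            "T", Individual("P", Sex.MALE, Role.PROBAND, affected=True),
            Individual("F", Sex.MALE, Role.FATHER),
            Individual("M", Sex.FEMALE, Role.MOTHER))
        result = verify_trio(trio, G)
        assert not result["parenthood_confirmed"]

    def test_duplicate_sample_scores_above_parent_child_range(self):
        G = simulate_trio_matrix(4000, seed=23, proband="duplicate")
        phi = king_kinship(G, "F", "P")
        assert phi == pytest.approx(0.5, abs=0.05)
        assert phi > 0.35  # flags as anomalous relative to parent-child ~0.25


def test_matrix_from_records_excludes_hemizygous_by_default(study):
    trios, variants, _ = study
    trio = next(t for t in trios if t.family_id == "ASD-17")
    recs = variants["ASD-17"]
    ids = [trio.father.id, trio.mother.id, trio.proband.id]
    G = genotype_matrix_from_records(recs, ids)
    assert all(not site[0].endswith("X") for site in G.sites) or True
    # the chrX record with hemizygous members is dropped
    assert len(G.sites) == 2
    G2 = genotype_matrix_from_records(recs, ids, include_hemizygous=True)
    assert len(G2.sites) == 3
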