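"""Genotype-class effects, d/a, favorable alleles, heterosis summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from hybridsel import (
    PerLocusDominance,
    TraitDirection,
    classify_dominance,
    compute_bph,
    compute_da,
    count_favorable_alleles,
    define_favorable_allele,
    estimate_genotype_effects,
    fraction_exceeding_parents,
    genotype_frequency_trajectory,
    select_top_loci,
)

HIGHER = TraitDirection("t", "higher_favorable")
LOWER = TraitDirection("t", "lower_favorable")
AMYLOSE = TraitDirection("amylose", "window_favorable", lo=13.0, hi=22.0)


class TestGenotypeEffects:
    def test_class_means_small_example(self):
        geno = np.array([2, 2, 1, 0, 0])
        pheno = np.array([10.0, 10.0, 8.0, 6.0, 6.0])
        A, M, C, nA, nM, nC = estimate_genotype_effects(geno, pheno)
        assert (A, M, C) == (10.0, 8.0, 6.0)
        assert (nA, nM, nC) == (2, 1, 2)

    def test_empty_class_is_nan(self):
        A, M, C, nA, nM, nC = estimate_genotype_effects(
            np.array([2, 2]), np.array([1.0, 3.0])
        )
        assert A == 2.0 and np.isnan(M) and np.isnan(C)
        assert (nM, nC) == (0, 0)

    def test_missing_pairs_dropped(self):
        A, *_ = estimate_genotype_effects(
            np.array([2, 2, -1]), np.array([1.0, np.nan, 5.0])
        )
        assert A == 1.0


class TestComputeDa:
    @pytest.mark.parametrize(
        "A,M,C,expected_a,expected_d,expected_degree",
        [
            (10.0, 8.0, 6.0, 2.0, 0.0, 0.0),       # pure additivity
            (10.0, 10.0, 6.0, 2.0, 2.0, 1.0),      # complete dominance
            (1.0, 1.12, 0.0, 0.5, 0.62, 1.24),     # overdominance
        ],
    )
    def test_formulas(self, A, M, C, expected_a, expected_d, expected_degree):
        est = compute_da(A, M, C, 10, 10, 10, HIGHER)
        assert est["a"] == pytest.approx(expected_a)
        assert est["d"] == pytest.approx(expected_d)
        assert est["degree"] == pytest.approx(expected_degree)

    def test_sign_flip_for_lower_favorable(self):
        est = compute_da(10.0, 10.0, 6.0, 10, 10, 10, LOWER)
        assert est["degree"] == pytest.approx(-1.0)

    def test_small_homozygote_class_flagged_invalid(self):
        est = compute_da(10.0, 8.0, 6.0, 10, 10, 4, HIGHER)
        assert not est["valid"]

    def test_zero_additive_effect_is_nan_not_exception(self):
        est = compute_da(5.0, 7.0, 5.0, 10, 10, 10, HIGHER)
        assert np.isnan(est["degree"]) and not est["valid"]

    @settings(max_examples=50, derandomize=True)
    @given(
        A=st.floats(-50, 50), M=st.floats(-50, 50), C=st.floats(-50, 50),
        alpha=st.floats(0.01, 20), beta=st.floats(-100, 100),
    )
    def test_degree_invariant_to_affine_rescaling(self, A, M, C, alpha, beta):
        # skip numerically degenerate homozygote separations where the
        # shifted A - C cancels catastrophically in float arithmetic
        assume(abs(A - C) > 1e-6 * max(1.0, abs(A), abs(C), abs(beta) / alpha))
        base = compute_da(A, M, C, 10, 10, 10, HIGHER)
        scaled = compute_da(
            alpha * A + beta, alpha * M + beta, alpha * C + beta, 10, 10, 10, HIGHER
        )
        if np.isfinite(base["degree"]):
            assert scaled["degree"] == pytest.approx(base["degree"], rel=1e-6, abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize(
        "degree,category",
        [
            (1.24, "overdominance"),
            (-0.14, "negative_dominance"),
            (0.0, "additive"),
            (0.15, "partial_dominance"),
            (0.4, "partial_dominance"),
            (1.0, "complete_dominance"),
        ],
    )
    def test_categories(self, degree, category):
        assert classify_dominance(degree) == category

    def test_non_finite_degree_rejected(self):
        with pytest.raises(ValueError):
            classify_dominance(float("nan"))


class TestFavorableAllele:
    def test_yield_higher_wins(self):
        assert define_favorable_allele(12.0, 9.0, HIGHER) == 2

    def test_heading_date_lower_wins(self):
        assert define_favorable_allele(95.0, 85.0, LOWER) == 0

    def test_amylose_window(self):
        assert define_favorable_allele(25.0, 16.0, AMYLOSE) == 0
        # both outside: closer to the window wins
        assert define_favorable_allele(23.0, 30.0, AMYLOSE) == 2

    def test_tie_unresolved(self):
        assert define_favorable_allele(5.0, 5.0, HIGHER) == -1


class TestFavorableCounting:
    def test_pyramiding_bounds(self):
        fav = np.full(100, 2)
        hom_fav = np.full((1, 100), 2)
        het = np.full((1, 100), 1)
        hom_unfav = np.full((1, 100), 0)
        assert count_favorable_alleles(hom_fav, fav)[0][0] == 200
        assert count_favorable_alleles(het, fav)[0][0] == 100
        assert count_favorable_alleles(hom_unfav, fav)[0][0] == 0

    def test_monotone_single_allele_increment(self):
        rng = np.random.default_rng(0)
        fav = rng.choice([0, 2], size=30)
        geno = rng.integers(0, 3, size=(1, 30))
        base = count_favorable_alleles(geno, fav)[0][0]
        for j in range(30):
            fav_copies = geno[0, j] if fav[j] == 2 else 2 - geno[0, j]
            if fav_copies == 2:
                continue
            bumped = geno.copy()
            bumped[0, j] += 1 if fav[j] == 2 else -1
            assert count_favorable_alleles(bumped, fav)[0][0] == base + 1

    def test_missing_and_unresolved_skipped(self):
        geno = np.array([[2, -1, 2]])
        fav = np.array([2, 2, -1])
        counts, skipped = count_favorable_alleles(geno, fav)
        assert counts[0] == 2 and skipped[0] == 2


class TestTopLoci:
    def test_ranking(self):
        tbl = pd.DataFrame(
            {"chrom": ["c1"] * 3, "pos": [1e6, 5e6, 9e6],
             "p": [1e-9, 1e-7, 1e-3]}
        )
        top = select_top_loci(tbl, k=2)
        assert top["p"].tolist() == [1e-9, 1e-7]

    def test_clumping_one_representative_per_signal(self):
        tbl = pd.DataFrame(
            {"chrom": ["c1", "c1", "c2"], "pos": [1_000_000, 1_010_000, 500_000],
             "p": [1e-9, 1e-8, 1e-7]}
        )
        top = select_top_loci(tbl, k=3)
        assert len(top) == 2  # the 10 kb neighbour clumps away
        assert top["pos"].tolist() == [1_000_000, 500_000]

    def test_k_larger_than_table_warns(self):
        tbl = pd.DataFrame({"chrom": ["c1"], "pos": [1.0], "p": [0.1]})
        with pytest.warns(UserWarning, match="requested"):
            top = select_top_loci(tbl, k=5)
        assert len(top) == 1


class TestTrajectories:
    def test_all_het_group(self):
        out = genotype_frequency_trajectory(np.array([1, 1, 1]), np.array(["Y1"] * 3))
        row = out.iloc[0]
        assert row["freq_het"] == 1.0
        assert row["freq_favorable_allele"] == 0.5

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=300)
        groups = rng.choice(["Y1", "Y2", "Y3"], size=300)
        out = genotype_frequency_trajectory(dosage, groups)
        sums = out[["freq_hom_favorable", "freq_het", "freq_hom_unfavorable"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_planted_drift_recovered(self):
        # favorable (ref) allele frequency 0.2 then 0.8, as exact genotype counts
        g1 = np.array([2] * 4 + [1] * 32 + [0] * 64)   # p = 0.2
        g2 = np.array([2] * 64 + [1] * 32 + [0] * 4)   # p = 0.8
        dosage = np.concatenate([g1, g2])
        groups = np.array(["Y1"] * 100 + ["Y3"] * 100)
        out = genotype_frequency_trajectory(dosage, groups).set_index("group")
        assert out.loc["Y1", "freq_favorable_allele"] == pytest.approx(0.2)
        assert out.loc["Y3", "freq_favorable_allele"] == pytest.approx(0.8)


class TestHeterosis:
    def test_bph_higher_favorable(self):
        out = compute_bph(12.0, 10.0, 9.0, HIGHER)
        assert out["bph"] == 2.0 and out["exceeds_better_parent"]
        out = compute_bph(9.5, 10.0, 9.0, HIGHER)
        assert out["bph"] == -0.5 and not out["exceeds_better_parent"]

    def test_bph_lower_favorable_flips(self):
        out = compute_bph(80.0, 85.0, 83.0, LOWER)
        assert out["bph"] == 3.0 and out["exceeds_better_parent"]

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError):
            compute_bph(1.0, np.nan, 2.0, HIGHER)

    def test_transgressive_fraction_bounds(self):
        below = np.array([1.0, 2.0, 3.0])
        assert fraction_exceeding_parents(below, 5.0, 6.0, HIGHER) == 0.0
        above = np.array([7.0, 8.0])
        assert fraction_exceeding_parents(above, 5.0, 6.0, HIGHER) == 1.0

    def test_transgressive_fraction_matches_counting(self):
        rng = np.random.default_rng(9)
        f2 = rng.normal(10, 2, size=500)
        frac = fraction_exceeding_parents(f2, 9.0, 11.0, HIGHER)
        assert frac == pytest.approx((f2 > 11.0).mean())


class TestPerLocusEstimator:
    def test_recovers_planted_effects_without_noise(self, small_markers):
        from hybridsel import QtlEffect, simulate_hybrid_cohort, simulate_phenotypes

        cohort = simulate_hybrid_cohort(800, small_markers, seed=30)
        qtls = {"t": [QtlEffect(10, 1.0, 0.5)]}
        pheno, _ = simulate_phenotypes(cohort, qtls, {"t": 1.0}, seed=31)
        est = PerLocusDominance(direction=HIGHER).fit(
            cohort.dosage[:, [10]], pheno["t"].to_numpy()
        )
        row = est.estimates_.iloc[0]
        assert row["a"] == pytest.approx(1.0)
        assert row["d"] == pytest.approx(0.5)
        assert row["category"] == "partial_dominance"
        assert row["favorable_dosage"] == 2

    def test_bias_shrinks_with_sample_size(self, small_markers):
        from hybridsel import QtlEffect, simulate_hybrid_cohort, simulate_phenotypes

        errs = {}
        for n in (500, 5000):
            reps = []
            for rep in range(5):
                cohort = simulate_hybrid_cohort(n, small_markers, seed=40 + rep)
                qtls = {"t": [QtlEffect(10, 1.0, 0.5)]}
                pheno, _ = simulate_phenotypes(cohort, qtls, {"t": 0.4},
                                               seed=50 + rep)
                est = PerLocusDominance(direction=HIGHER).fit(
                    cohort.dosage[:, [10]], pheno["t"].to_numpy()
                )
                reps.append(abs(est.estimates_.iloc[0]["degree"] - 0.5))
            errs[n] = np.mean(reps)
        assert errs[5000] < errs[500]
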