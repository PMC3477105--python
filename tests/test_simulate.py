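"""Unit and property tests for the two-locus generative model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit
from scipy.stats import chi2_contingency

from ipmeta import (
    DiseaseModel,
    LDSpec,
    TraitModel,
    ascertain_case_control,
    build_scenario,
    calibrate_gamma0,
    calibrate_gamma2,
    effect_from_heritability,
    expected_incidence,
    haplotype_frequencies,
    sample_joint_genotypes,
    simulate_disease,
    simulate_trait,
)
from ipmeta.simulate import hwe_genotype_freqs

HWE_03 = hwe_genotype_freqs(0.3)


class TestHaplotypeFrequencies:
    @pytest.mark.parametrize(
        "m1,q1,r,expected",
        [
            (0.3, 0.3, 0.0, (0.09, 0.21, 0.21, 0.49)),
            (0.3, 0.3, 0.8, (0.258, 0.042, 0.042, 0.658)),
        ],
    )
    def test_known_tables(self, m1, q1, r, expected):
        np.testing.assert_allclose(
            haplotype_frequencies(LDSpec(m1, q1, r)), expected, atol=1e-12
        )

    def test_infeasible_r_names_the_bound(self):
        # D = 0.135 exceeds the feasible maximum 0.05, i.e. r_max = 1/3
        with pytest.raises(ValueError, match="0.3333"):
            haplotype_frequencies(LDSpec(0.1, 0.5, 0.9))

    @given(
        m1=st.floats(0.01, 0.99),
        q1=st.floats(0.01, 0.99),
        u=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_simplex_and_correlation_roundtrip(self, m1, q1, u):
        """Frequencies form a simplex and the 2x2 table's allele-indicator
        correlation recovers r (brute-force check of the D parameterization)."""
        ld = LDSpec(m1, q1, u * LDSpec(m1, q1, 0).max_r)
        f = haplotype_frequencies(ld)
        assert np.all(f >= 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        # indicator correlation from the table: cov = f11 - m1*q1
        cov = f[0] - m1 * q1
        corr = cov / np.sqrt(m1 * (1 - m1) * q1 * (1 - q1))
        assert corr == pytest.approx(ld.r, abs=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LDSpec(0.0, 0.3, 0.5)
        with pytest.raises(ValueError):
            LDSpec(0.3, 0.3, 1.5)


class TestJointGenotypes:
    def test_perfect_ld_equal_mafs_gives_identical_genotypes(self, rng):
        g_dis, g_mark = sample_joint_genotypes(LDSpec(0.3, 0.3, 1.0), 5000, rng)
        np.testing.assert_array_equal(g_dis, g_mark)

    @pytest.mark.parametrize("r", [0.0, 0.8])
    def test_sample_correlation_matches_r(self, r, rng):
        g_dis, g_mark = sample_joint_genotypes(LDSpec(0.3, 0.3, r), 100_000, rng)
        rho = np.corrcoef(g_dis, g_mark)[0, 1]
        assert rho == pytest.approx(r, abs=0.01)

    def test_hardy_weinberg_marginals(self, rng):
        g_dis, g_mark = sample_joint_genotypes(LDSpec(0.3, 0.2, 0.5), 200_000, rng)
        for g, q in [(g_dis, 0.2), (g_mark, 0.3)]:
            freqs = np.bincount(g, minlength=3) / len(g)
            np.testing.assert_allclose(freqs, hwe_genotype_freqs(q), atol=0.005)


class TestTraitModel:
    def test_zero_heritability(self):
        assert effect_from_heritability(0.0, "additive", HWE_03, 2.5) == (0.0, 2.5)

    def test_additive_closed_form(self):
        # Var(additive code) = 2 * 0.3 * 0.7 = 0.42
        beta1, s2e = effect_from_heritability(0.010, "additive", HWE_03, 1.0)
        assert beta1 == pytest.approx(np.sqrt(0.010 / 0.42), rel=1e-12)
        assert s2e == pytest.approx(0.99)

    def test_recessive_closed_form(self):
        # recessive indicator has success probability 0.3^2 = 0.09
        beta1, _ = effect_from_heritability(0.010, "recessive", HWE_03, 1.0)
        assert beta1 == pytest.approx(np.sqrt(0.010 / (0.09 * 0.91)), rel=1e-12)

    @pytest.mark.parametrize("coding", ["additive", "dominant", "recessive"])
    def test_simulated_variance_explained(self, coding, rng):
        """Empirical genetic variance over 10^6 genotypes matches h2."""
        h2 = 0.008
        beta1, s2e = effect_from_heritability(h2, coding, HWE_03, 1.0)
        tm = TraitModel(coding=coding, h2=h2, beta1=beta1, sigma2_E=s2e)
        g = rng.choice(3, size=1_000_000, p=HWE_03)
        y = simulate_trait(g, tm, rng)
        from ipmeta.simulate import code_genotypes

        genetic = beta1 * code_genotypes(g, coding)
        assert np.var(genetic) / np.var(y) == pytest.approx(h2, abs=3 * h2 / 30)

    def test_h2_out_of_range(self):
        with pytest.raises(ValueError):
            effect_from_heritability(1.0, "additive", HWE_03)

    def test_unmediated_model_has_no_genotype_effect(self):
        tm = TraitModel.from_heritability(0.010, "additive", HWE_03, mediated=False)
        assert tm.beta1 == 0.0
        assert tm.sigma2_E == 1.0

    def test_noiseless_trait_is_affine_in_genotype(self, rng):
        tm = TraitModel(beta0=2.0, beta1=1.0, sigma2_E=1e-30, h2=0.0)
        g = np.array([0, 1, 2, 1])
        np.testing.assert_allclose(simulate_trait(g, tm, rng), [2, 3, 4, 3])

    def test_null_trait_independent_of_genotype(self, rng):
        tm = TraitModel(beta0=0.0, beta1=0.0, sigma2_E=1.0)
        g = rng.choice(3, size=50_000, p=HWE_03)
        y = simulate_trait(g, tm, rng)
        slope = np.polyfit(g.astype(float), y, 1)[0]
        assert slope == pytest.approx(0.0, abs=0.02)


class TestCalibration:
    def test_gamma0_closed_form_without_covariates(self):
        tm = TraitModel()
        g0 = calibrate_gamma0(DiseaseModel(0, 0, 0), tm, HWE_03, 0.05)
        assert g0 == pytest.approx(logit(0.05), abs=1e-8)

    def test_gamma0_monte_carlo(self, rng):
        """Quadrature-calibrated intercept reproduces the incidence by simulation."""
        tm = TraitModel()
        dm = DiseaseModel(0.0, np.log(1.20), 0.0, "additive")
        g0 = calibrate_gamma0(dm, tm, HWE_03, 0.05)
        dm = DiseaseModel(g0, dm.gamma1, dm.gamma2, dm.coding)
        g = rng.choice(3, size=1_000_000, p=HWE_03)
        y = simulate_trait(g, tm, rng)
        d = simulate_disease(g, y, dm, rng)
        assert d.mean() == pytest.approx(0.05, abs=0.002)

    def test_gamma2_zero_when_target_already_met(self):
        tm = TraitModel()
        g2 = calibrate_gamma2(logit(0.05), 0.0, tm, HWE_03, 0.05)
        assert g2 == pytest.approx(0.0, abs=1e-6)

    def test_gamma2_table_scenario_monte_carlo(self, rng):
        """gamma0 = -3.36, gamma1 = log 1.20: the calibrated gamma2 is a unique
        positive root and the simulated incidence hits 0.05."""
        tm = TraitModel()
        g2 = calibrate_gamma2(-3.36, np.log(1.20), tm, HWE_03, 0.05)
        assert g2 > 0
        dm = DiseaseModel(-3.36, np.log(1.20), g2, "additive")
        g = rng.choice(3, size=1_000_000, p=HWE_03)
        y = simulate_trait(g, tm, rng)
        d = simulate_disease(g, y, dm, rng)
        assert d.mean() == pytest.approx(0.05, abs=0.002)

    def test_gamma2_unreachable_target(self):
        # at gamma0 = 0 the incidence is already ~0.5 > 0.05
        with pytest.raises(ValueError, match="above"):
            calibrate_gamma2(0.0, 0.0, TraitModel(), HWE_03, 0.05)

    def test_quadrature_matches_direction_of_gamma2(self):
        tm = TraitModel()
        low = expected_incidence(DiseaseModel(-3.36, 0.18, 0.0), tm, HWE_03)
        high = expected_incidence(DiseaseModel(-3.36, 0.18, 1.0), tm, HWE_03)
        assert low < 0.05 < high


class TestDiseaseSimulation:
    def test_marginal_rate_without_effects(self, rng):
        dm = DiseaseModel(logit(0.05), 0.0, 0.0)
        d = simulate_disease(
            np.zeros(1_000_000, dtype=int), np.zeros(1_000_000), dm, rng
        )
        assert d.mean() == pytest.approx(0.05, abs=0.001)

    def test_heterozygote_odds_ratio(self, rng):
        """Direct-path OR of heterozygotes vs reference recovers exp(gamma1)."""
        dm = DiseaseModel(-2.0, np.log(1.20), 0.0, "additive")
        g = rng.choice(3, size=2_000_000, p=HWE_03)
        d = simulate_disease(g, np.zeros(len(g)), dm, rng)
        odds = [
            d[g == k].mean() / (1 - d[g == k].mean()) for k in (0, 1)
        ]
        assert odds[1] / odds[0] == pytest.approx(1.20, abs=0.02)

    def test_degenerate_intercept_gives_no_cases(self, rng):
        dm = DiseaseModel(-100.0, 0.0, 0.0)
        d = simulate_disease(np.zeros(1000, dtype=int), np.zeros(1000), dm, rng)
        assert d.sum() == 0


class TestAscertainment:
    def test_exact_counts(self, rng):
        sc = build_scenario("medium", "additive", 3, r=0.4, h2=0.006)
        cc = ascertain_case_control(sc, n_cases=500, n_controls=700, rng=rng)
        assert cc.d.sum() == 500
        assert len(cc) - cc.d.sum() == 700
        assert set(np.unique(cc.g_marker)) <= {0, 1, 2}

    def test_null_marker_distribution_same_in_cases_and_controls(self, rng):
        sc = build_scenario("medium", "additive", 3, r=0.0, h2=0.010)
        cc = ascertain_case_control(sc, rng=rng)
        table = np.array(
            [
                np.bincount(cc.g_marker[cc.d == 1], minlength=3),
                np.bincount(cc.g_marker[cc.d == 0], minlength=3),
            ]
        )
        assert chi2_contingency(table).pvalue > 0.001

    def test_case_maf_exceeds_control_maf_under_ld(self, rng):
        """Directional check: with r = 0.8 and a dual-pathway model the risk
        allele is enriched in cases; mean difference over 10 cohorts."""
        sc = build_scenario("medium", "additive", 3, r=0.8, h2=0.010)
        diffs = []
        for _ in range(10):
            cc = ascertain_case_control(sc, n_cases=1000, n_controls=1000, rng=rng)
            diffs.append(
                cc.g_marker[cc.d == 1].mean() / 2 - cc.g_marker[cc.d == 0].mean() / 2
            )
        assert np.mean(diffs) > 0

    def test_draw_cap(self):
        sc = build_scenario("medium", "additive", 3, r=0.0, h2=0.010)
        with pytest.raises(RuntimeError, match="cap"):
            ascertain_case_control(
                sc, n_cases=100, n_controls=100, rng=1, max_draw_factor=0.5
            )


def test_marker_and_disease_locus_tests_coincide_at_perfect_ld(rng):
    """r = 1 with equal MAFs: statistics computed at the marker equal those
    computed at the disease locus on the same cohort."""
    from ipmeta import linear_assoc_adjusted, logistic_assoc

    sc = build_scenario("medium", "additive", 3, r=1.0, h2=0.010)
    cc = ascertain_case_control(sc, n_cases=800, n_controls=800, rng=rng)
    r_mark = logistic_assoc(cc.d, cc.g_marker)
    r_dis = logistic_assoc(cc.d, cc.g_disease)
    assert r_mark == r_dis
    l_mark = linear_assoc_adjusted(cc.y, cc.g_marker, cc.d)
    l_dis = linear_assoc_adjusted(cc.y, cc.g_disease, cc.d)
    assert l_mark == l_dis
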