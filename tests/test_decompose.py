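"""Breeding values, variance components and relative covariances, all approaches."""

import numpy as np
import pytest

from conftest import TABLE6_EXPECTED, random_model
from imprintqg import (
    GENOTYPES,
    Approach,
    ImprintingLocus,
    PopulationState,
    additive_effects_2a,
    alphas,
    breeding_values,
    dominance_deviations,
    genotype_frequencies,
    oracle_breeding_values,
    oracle_relative_covariances,
    regression_breeding_values,
    relative_covariances,
    total_genetic_variance,
    variance_components,
)
from imprintqg.reporting import round_printed, scenario_cells

G11, G21, G12, G22 = GENOTYPES
ALL = list(Approach)


class TestBreedingValues:
    def test_a1_homozygote_value(self, paternal_scenario):
        bv = breeding_values(*paternal_scenario, Approach.A1)
        assert bv.values[G11] == pytest.approx(-0.5)

    def test_a2a_reciprocal_heterozygotes_differ(self, paternal_scenario):
        bv = breeding_values(*paternal_scenario, Approach.A2a)
        assert bv.values[G21] == pytest.approx(0.425)
        assert bv.values[G12] == pytest.approx(-0.425)

    def test_a1_equals_a2b_everywhere(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            locus, pop = random_model(rng)
            b1 = breeding_values(locus, pop, Approach.A1)
            b2 = breeding_values(locus, pop, Approach.A2b)
            for g in GENOTYPES:
                assert b1.values[g] == b2.values[g]
                assert b1.female[g] == b2.female[g]
                assert b1.male[g] == b2.male[g]

    def test_mendelian_case_all_approaches_identical(self):
        locus, pop = ImprintingLocus(0.7, 0.4, 0.4), PopulationState(0.3)
        tables = [breeding_values(locus, pop, ap).values for ap in ALL]
        for other in tables[1:]:
            for g in GENOTYPES:
                assert other[g] == pytest.approx(tables[0][g], abs=1e-12)

    def test_zero_mean_and_het_mean_row(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            locus, pop = random_model(rng)
            freqs = genotype_frequencies(pop)
            af, am = alphas(locus, pop)
            expected_het = 0.5 * (pop.p1 - pop.p2) * (af + am)
            for ap in ALL:
                bv = breeding_values(locus, pop, ap)
                mean = sum(freqs[g] * bv.values[g] for g in GENOTYPES)
                assert mean == pytest.approx(0.0, abs=1e-12)
                assert bv.het_mean == pytest.approx(expected_het, abs=1e-12)
                assert 0.5 * (bv.values[G21] + bv.values[G12]) == pytest.approx(
                    expected_het, abs=1e-12
                )

    def test_a1_matches_offspring_mean_reconstruction(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            locus, pop = random_model(rng)
            closed = breeding_values(locus, pop, Approach.A1)
            recon = oracle_breeding_values(locus, pop)
            for g in GENOTYPES:
                assert recon["female"][g] == pytest.approx(closed.female[g], abs=1e-12)
                assert recon["male"][g] == pytest.approx(closed.male[g], abs=1e-12)

    def test_regression_reconstruction_matches_closed_forms(self):
        rng = np.random.default_rng(24)
        for _ in range(50):
            locus, pop = random_model(rng)
            for ap in (Approach.A3a, Approach.A3b):
                fitted = regression_breeding_values(locus, pop, ap)
                closed = breeding_values(locus, pop, ap)
                for g in GENOTYPES:
                    assert fitted[g] == pytest.approx(closed.values[g], abs=1e-9)

    def test_inbred_population_rejected(self):
        with pytest.raises(ValueError, match="f = 0"):
            breeding_values(
                ImprintingLocus(0.5, 0.1, 0.2), PopulationState(0.4, f=0.3), Approach.A1
            )


class TestAdditiveEffects:
    def test_symmetric_additive_case(self):
        eps = additive_effects_2a(ImprintingLocus(0.5, 0, 0), PopulationState(0.5))
        assert eps == pytest.approx((-0.25, 0.25, -0.25, 0.25))

    def test_paternal_inactivation_maternal_effects(self, paternal_scenario):
        eps = additive_effects_2a(*paternal_scenario)
        assert eps.eps_1_maternal == pytest.approx(-0.4625)
        assert eps.eps_2_maternal == pytest.approx(0.4625)

    def test_effects_are_deviations(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            locus, pop = random_model(rng)
            eps = additive_effects_2a(locus, pop)
            assert pop.p1 * eps.eps_1_maternal + pop.p2 * eps.eps_2_maternal == (
                pytest.approx(0.0, abs=1e-12)
            )
            assert pop.p1 * eps.eps_1_paternal + pop.p2 * eps.eps_2_paternal == (
                pytest.approx(0.0, abs=1e-12)
            )


class TestDominanceDeviations:
    def test_additive_model_has_no_deviations(self):
        dd = dominance_deviations(
            ImprintingLocus(0.5, 0, 0), PopulationState(0.3), Approach.A2a
        )
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in dd.values.values())

    def test_a2a_deviation_variance_matches_closed_form(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            locus, pop = random_model(rng)
            dd = dominance_deviations(locus, pop, Approach.A2a)
            freqs = genotype_frequencies(pop)
            var = sum(freqs[g] * dd.values[g] ** 2 for g in GENOTYPES)
            expected = (locus.a * pop.p1 * pop.p2 * (locus.k1 + locus.k2)) ** 2
            assert var == pytest.approx(expected, abs=1e-12)

    def test_a2b_sex_specific_deviations_have_zero_mean(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            locus, pop = random_model(rng)
            dd = dominance_deviations(locus, pop, Approach.A2b)
            freqs = genotype_frequencies(pop)
            for table in (dd.female, dd.male):
                mean = sum(freqs[g] * table[g] for g in GENOTYPES)
                assert mean == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("approach", [Approach.A1, Approach.A3a, Approach.A3b])
    def test_only_defined_for_a2a_a2b(self, approach):
        with pytest.raises(ValueError, match="A2a/A2b"):
            dominance_deviations(
                ImprintingLocus(0.5, 0.2, -0.1), PopulationState(0.5), approach
            )


class TestVarianceComponents:
    @pytest.mark.parametrize("scenario", ["paternal_inactivation", "maternal_inactivation"])
    @pytest.mark.parametrize("group", ["A1_2b", "A2a_3b", "A3a"])
    def test_worked_scenarios_match_printed_values(self, scenario, group, request):
        fixture = {
            "paternal_inactivation": "paternal_scenario",
            "maternal_inactivation": "maternal_scenario",
        }[scenario]
        locus, pop = request.getfixturevalue(fixture)
        approach = {"A1_2b": Approach.A1, "A2a_3b": Approach.A2a, "A3a": Approach.A3a}[group]
        cells = scenario_cells(locus, pop, approach)
        for row, expected in TABLE6_EXPECTED[scenario][group].items():
            if expected is None:
                assert cells[row] is None
            else:
                assert round_printed(cells[row], 4) == pytest.approx(expected, abs=5e-13)

    def test_no_imprinting_no_dominance_is_purely_additive(self):
        locus, pop = ImprintingLocus(0.5, 0, 0), PopulationState(0.3)
        expected = 2 * 0.3 * 0.7 * 0.25
        for ap in ALL:
            c = variance_components(locus, pop, ap)
            assert c.sigma2_D == pytest.approx(0.0, abs=1e-15)
            assert c.sigma_AD_f == c.sigma_AD_m == 0.0
            assert c.sigma2_A_f == pytest.approx(expected)
            assert c.sigma2_A_m == pytest.approx(expected)

    def test_partition_sums_to_total_for_every_approach(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            locus, pop = random_model(rng)
            total = total_genetic_variance(locus, pop)
            for ap in ALL:
                c = variance_components(locus, pop, ap)
                assert c.sigma2_A + c.sigma2_D + c.sigma_AD_f + c.sigma_AD_m == (
                    pytest.approx(total, abs=1e-12)
                )

    def test_ad_covariance_sum_is_nonpositive(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            locus, pop = random_model(rng)
            c = variance_components(locus, pop, Approach.A1)
            expected = -(locus.a**2) * pop.p1 * pop.p2 * (locus.k1 - locus.k2) ** 2
            assert c.sigma_AD_f + c.sigma_AD_m == pytest.approx(expected, abs=1e-12)
            assert c.sigma_AD_f + c.sigma_AD_m <= 1e-15

    def test_label_swap_leaves_variances_unchanged(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            locus, pop = random_model(rng)
            # exchange allele labels: p1 <-> p2 and re-anchor the value scale
            relabeled = ImprintingLocus(a=-locus.a, k1=-locus.k2, k2=-locus.k1)
            flipped = PopulationState(p1=pop.p2)
            for ap in ALL:
                c = variance_components(locus, pop, ap)
                d = variance_components(relabeled, flipped, ap)
                assert d.sigma2_A_f == pytest.approx(c.sigma2_A_f, abs=1e-12)
                assert d.sigma2_A_m == pytest.approx(c.sigma2_A_m, abs=1e-12)
                assert d.sigma2_D == pytest.approx(c.sigma2_D, abs=1e-12)
                assert d.sigma2_G == pytest.approx(c.sigma2_G, abs=1e-12)


class TestRelativeCovariances:
    def test_additive_case_parent_offspring_is_half_additive_variance(self):
        covs = relative_covariances(
            ImprintingLocus(0.5, 0, 0), PopulationState(0.5), Approach.A1
        )
        assert covs.cov_mother_offspring == pytest.approx(0.0625)
        assert covs.cov_father_offspring == pytest.approx(0.0625)

    def test_swapping_ks_swaps_maternal_and_paternal_entries(self):
        rng = np.random.default_rng(51)
        for _ in range(25):
            locus, pop = random_model(rng)
            c = relative_covariances(locus, pop, Approach.A1)
            s = relative_covariances(locus.swapped(), pop, Approach.A1)
            assert s.cov_mother_offspring == pytest.approx(c.cov_father_offspring, abs=1e-12)
            assert s.cov_halfsib_maternal == pytest.approx(c.cov_halfsib_paternal, abs=1e-12)
            assert s.cov_fullsib == pytest.approx(c.cov_fullsib, abs=1e-12)

    def test_closed_forms_match_enumeration(self):
        rng = np.random.default_rng(52)
        for _ in range(50):
            locus, pop = random_model(rng)
            closed = relative_covariances(locus, pop, Approach.A1)
            oracle = oracle_relative_covariances(locus, pop)
            for field in (
                "cov_mother_offspring",
                "cov_father_offspring",
                "cov_fullsib",
                "cov_halfsib_maternal",
                "cov_halfsib_paternal",
            ):
                assert getattr(closed, field) == pytest.approx(
                    getattr(oracle, field), abs=1e-12
                )

    def test_pooled_approaches_follow_kinship_identities(self):
        rng = np.random.default_rng(53)
        for _ in range(25):
            locus, pop = random_model(rng)
            for ap in (Approach.A2a, Approach.A3a, Approach.A3b):
                c = variance_components(locus, pop, ap)
                r = relative_covariances(locus, pop, ap)
                assert r.cov_mother_offspring == pytest.approx(0.5 * c.sigma2_A, abs=1e-12)
                assert r.cov_halfsib_maternal == pytest.approx(0.25 * c.sigma2_A, abs=1e-12)
                assert r.cov_fullsib == pytest.approx(
                    0.5 * c.sigma2_A + 0.25 * c.sigma2_D, abs=1e-12
                )


def test_unknown_approach_label_rejected():
    with pytest.raises(ValueError, match="unknown approach"):
        variance_components(ImprintingLocus(0.5, 0, 0), PopulationState(0.5), "A4")
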