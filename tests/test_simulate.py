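import numpy as np
import pytest
from scipy.special import logit

import collidersim as cs
from collidersim.simulate import CALIBRATION_SEED


class TestCalibration:
    def test_null_model_closed_forms(self):
        # with no covariate effects the intercept is the logit of the target
        null = cs.ScenarioSpec(or_a_incidence=1.0, or_c_incidence=1.0,
                               or_u_incidence=1.0, beta_u_progression=0.0,
                               target_prevalence=0.5)
        assert cs.calibrate_intercept(null) == pytest.approx(0.0, abs=1e-6)
        null02 = null.with_(target_prevalence=0.2)
        assert cs.calibrate_intercept(null02) == pytest.approx(
            logit(0.2), abs=1e-6)

    def test_calibrated_prevalence_hits_target(self):
        spec = cs.preset("low", seed=3)
        alpha = cs.calibrate_intercept(spec)
        prev = np.mean([cs.simulate_population(spec, r, intercept=alpha)
                        .disease.mean() for r in range(10)])
        assert 0.195 <= prev <= 0.205

    def test_intercept_independent_of_master_seed(self):
        a1 = cs.calibrate_intercept(cs.preset("high", seed=1))
        a2 = cs.calibrate_intercept(cs.preset("high", seed=999))
        assert a1 == a2

    def test_small_calibration_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.calibrate_intercept(cs.preset("low"), calibration_size=10_000)


class TestSimulatePopulation:
    def test_bit_reproducibility(self):
        spec = cs.preset("moderate", seed=42)
        p1 = cs.simulate_population(spec, 7)
        p2 = cs.simulate_population(spec, 7)
        for name in ("genotype_a", "c", "u", "disease", "progression",
                     "incidence_probability"):
            np.testing.assert_array_equal(getattr(p1, name), getattr(p2, name))
        p3 = cs.simulate_population(spec, 8)
        assert not np.array_equal(p1.progression, p3.progression)

    def test_case_count_near_expected_prevalence(self):
        spec = cs.preset("low", seed=5)
        pop = cs.simulate_population(spec, 0)
        n = spec.n_individuals
        expected = 0.2 * n
        slack = 4 * np.sqrt(n * 0.2 * 0.8)
        assert abs(pop.n_cases - expected) < slack

    def test_independent_dag_leaves_no_correlations(self):
        spec = cs.ScenarioSpec(or_a_incidence=1.0, or_c_incidence=1.0,
                               or_u_incidence=1.0, beta_u_progression=0.0,
                               seed=9)
        pop = cs.simulate_population(spec, 0)
        bound = 4 / np.sqrt(len(pop))
        for x, y in [(pop.genotype_a, pop.u), (pop.genotype_a, pop.c),
                     (pop.c, pop.u)]:
            assert abs(np.corrcoef(x, y)[0, 1]) < bound
        mask = pop.case_mask
        assert abs(np.corrcoef(pop.genotype_a[mask], pop.u[mask])[0, 1]) \
            < 4 / np.sqrt(mask.sum())

    def test_full_population_covariates_uncorrelated_under_presets(self):
        pop = cs.simulate_population(cs.preset("strong", seed=13), 0)
        bound = 4 / np.sqrt(len(pop))
        assert abs(np.corrcoef(pop.genotype_a, pop.u)[0, 1]) < bound
        assert abs(np.corrcoef(pop.genotype_a, pop.c)[0, 1]) < bound

    @pytest.mark.parametrize("label", ["low", "strong"])
    def test_case_selection_induces_negative_a_u_correlation(self, label):
        # same-direction incidence effects => negative induced association
        spec = cs.preset(label, seed=17)
        r = np.mean([
            np.corrcoef(p.genotype_a[p.case_mask], p.u[p.case_mask])[0, 1]
            for p in (cs.simulate_population(spec, i) for i in range(5))
        ])
        assert r < 0

    def test_degenerate_replicate_flagged(self):
        tiny = cs.ScenarioSpec(n_individuals=100, target_prevalence=0.05,
                               seed=23)
        flagged = [cs.simulate_population(tiny, r).is_degenerate
                   for r in range(20)]
        assert any(flagged)

    def test_progression_generated_for_everyone(self):
        pop = cs.simulate_population(cs.preset("low", seed=2), 0)
        assert np.isfinite(pop.progression).all()
        assert len(pop.progression) == len(pop)

    def test_variant_b_optional_and_progression_shifts(self):
        spec = cs.preset("low", seed=31, include_b=True)
        pop = cs.simulate_population(spec, 0)
        assert pop.genotype_b is not None
        slope = cs.full_cohort_effect(pop, "B")
        assert slope.coefficient == pytest.approx(
            spec.beta_b_progression, abs=4 * slope.se)


class TestMRSimulation:
    def test_no_collider_path_no_induced_association(self):
        mr = cs.MRScenarioSpec(or_exposure_incidence=1.0,
                               or_confounder_incidence=1.0, seed=3)
        pop = cs.simulate_mr_population(mr, 0)
        mask = pop.case_mask
        r = np.corrcoef(pop.genotype_a[mask], pop.u[mask])[0, 1]
        assert abs(r) < 4 / np.sqrt(mask.sum())

    def test_selection_on_exposure_caused_disease_biases_instrument(self):
        # null true effect, exposure causes incidence, confounder on
        # exposure and progression: instrument-progression association
        # among cases is nonzero
        mr = cs.MRScenarioSpec(seed=4, beta_exposure_progression=0.0)
        coefs = []
        for r in range(20):
            pop = cs.simulate_mr_population(mr, r)
            coefs.append(cs.case_only_effect(pop, "Z").coefficient)
        mean = np.mean(coefs)
        mcse = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
        assert abs(mean) > 3 * mcse

    def test_mr_population_exports_exposure(self):
        pop = cs.simulate_mr_population(cs.MRScenarioSpec(seed=5), 0)
        assert pop.exposure is not None
        assert "exposure" in pop.to_frame().columns
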