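import numpy as np
import pytest

import collidersim as cs
from conftest import mean_and_mcse


class TestVariantIncidenceCheck:
    def test_recovers_generative_log_odds_for_a(self):
        spec = cs.preset("low", seed=19, n_individuals=400_000)
        pop = cs.simulate_population(spec, 0)
        est = cs.variant_incidence_check(pop, "A")
        # marginal (unadjusted) log-OR is mildly attenuated relative to the
        # conditional log(1.3) by the normal covariates; 4 SE around it
        assert est.coefficient == pytest.approx(np.log(1.3), abs=0.03)

    def test_progression_only_variant_is_null(self):
        spec = cs.preset("low", seed=19, include_b=True)
        pop = cs.simulate_population(spec, 0)
        est = cs.variant_incidence_check(pop, "B")
        assert abs(est.coefficient) < 4 * est.se

    def test_null_variant_in_null_model(self):
        spec = cs.ScenarioSpec(or_a_incidence=1.0, or_c_incidence=1.0,
                               or_u_incidence=1.0, beta_u_progression=0.0,
                               seed=20)
        pop = cs.simulate_population(spec, 0)
        est = cs.variant_incidence_check(pop, "A")
        assert abs(est.coefficient) < 4 * est.se


class TestVariantConfounderCheck:
    def test_null_in_full_population_negative_in_cases(self):
        spec = cs.preset("strong", seed=21)
        pairs = [cs.variant_confounder_check(cs.simulate_population(spec, r),
                                             "A", "C") for r in range(60)]
        full_mean, full_mcse = mean_and_mcse([p.full.coefficient for p in pairs])
        case_mean, case_mcse = mean_and_mcse([p.cases.coefficient for p in pairs])
        assert abs(full_mean) < 4 * full_mcse
        assert case_mean < -3 * case_mcse

    def test_no_induced_path_when_c_does_not_affect_incidence(self):
        spec = cs.preset("strong", seed=22).with_(or_c_incidence=1.0)
        pairs = [cs.variant_confounder_check(cs.simulate_population(spec, r),
                                             "A", "C") for r in range(10)]
        case_mean, case_mcse = mean_and_mcse([p.cases.coefficient for p in pairs])
        assert abs(case_mean) < 4 * case_mcse


class TestAdjustedCaseOnly:
    def test_adjustment_restores_null_when_confounding_all_measured(self):
        via_c = cs.ScenarioSpec(or_u_incidence=1.0, beta_u_progression=0.0,
                                or_c_incidence=2.0, beta_c_progression=0.5,
                                seed=25)
        ests = [cs.adjusted_case_only_effect(cs.simulate_population(via_c, r))
                for r in range(30)]
        mean, mcse = mean_and_mcse([e.coefficient for e in ests])
        assert abs(mean) < 4 * mcse

    def test_unmeasured_confounding_survives_adjustment(self):
        spec = cs.preset("strong", seed=26)
        ests = [cs.adjusted_case_only_effect(cs.simulate_population(spec, r))
                for r in range(30)]
        mean, mcse = mean_and_mcse([e.coefficient for e in ests])
        assert mean < -3 * mcse

    def test_adjustment_leaves_b_unbiased(self):
        spec = cs.preset("strong", seed=27, include_b=True)
        ests = [cs.adjusted_case_only_effect(cs.simulate_population(spec, r),
                                             "B") for r in range(20)]
        mean, mcse = mean_and_mcse([e.coefficient for e in ests])
        assert mean == pytest.approx(spec.beta_b_progression, abs=4 * mcse)


class TestIPW:
    def test_constant_weights_reduce_to_unweighted_fit(self, strong_pop):
        pop = strong_pop
        unweighted = cs.case_only_effect(pop, "A")
        # uniform incidence probability => constant weights
        import copy
        flat = copy.copy(pop)
        flat.incidence_probability = np.full(len(pop), 0.2)
        weighted = cs.ipw_case_only_effect(flat, "A", "true_probabilities")
        assert weighted.coefficient == pytest.approx(unweighted.coefficient,
                                                     abs=1e-10)

    def test_true_probability_weights_remove_collider_bias(self):
        spec = cs.preset("strong", seed=28, n_individuals=20_000)
        coefs = [cs.ipw_case_only_effect(cs.simulate_population(spec, r),
                                         "A").coefficient for r in range(60)]
        mean, mcse = mean_and_mcse(coefs)
        assert abs(mean) < 4 * mcse

    def test_weights_fitted_without_u_reduce_but_keep_bias(self):
        spec = cs.preset("strong", seed=29, n_individuals=20_000)
        raw, part = [], []
        for r in range(60):
            pop = cs.simulate_population(spec, r)
            raw.append(cs.case_only_effect(pop, "A").coefficient)
            part.append(cs.ipw_case_only_effect(pop, "A", ["A", "C"]).coefficient)
        raw_mean, _ = mean_and_mcse(raw)
        part_mean, part_mcse = mean_and_mcse(part)
        assert abs(part_mean) < abs(raw_mean)     # bias reduced ...
        assert part_mean < -3 * part_mcse         # ... but not removed

    def test_extreme_weight_ratio_warns_and_can_truncate(self, strong_pop):
        with pytest.warns(UserWarning, match="ratio"):
            cs.ipw_case_only_effect(strong_pop, "A", max_weight_ratio=1.5)
        with pytest.warns(UserWarning, match="truncated"):
            est = cs.ipw_case_only_effect(strong_pop, "A",
                                          max_weight_ratio=1.5, truncate=True)
        assert np.isfinite(est.coefficient)

    def test_robust_se_flag_changes_only_the_se(self, strong_pop):
        plain = cs.ipw_case_only_effect(strong_pop, "A")
        robust = cs.ipw_case_only_effect(strong_pop, "A", robust_se=True)
        assert robust.coefficient == pytest.approx(plain.coefficient, abs=1e-10)
        assert robust.se != plain.se


def test_checklist_report_structure(strong_pop):
    rep = cs.checklist_report(strong_pop)
    assert set(rep["item"]) == {1, 2, 3, 4}
    assert set(rep["flag"]) <= {"pass", "warn"}
    # item 1 must flag A: it is a genuine incidence variant
    assert (rep.loc[rep["item"] == 1, "flag"] == "warn").all()
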