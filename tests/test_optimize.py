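import math

import numpy as np
import pytest

from tubopt import (IsotypeProfile, brute_force_oracle, evaluate_drug,
                    normalize, optimize_dot, optimize_kl, optimize_penalized)

from .conftest import random_profile


def pure(i, label=""):
    v = np.zeros(8)
    v[i] = 1.0
    return IsotypeProfile(v, label)


def random_instance(rng, support, n_constraints=2, cap_low=0.1, cap_high=0.6):
    q_c = random_profile(rng, support, "cancer")
    cons = []
    for k in range(n_constraints):
        q_h = random_profile(rng, support, f"h{k}")
        cons.append((q_h, float(rng.uniform(cap_low, cap_high))))
    return q_c, cons


class TestDotLP:
    def test_unconstrained_is_argmax_indicator(self):
        q = normalize([0.6, 0.3, 0.1, 0, 0, 0, 0, 0], "c")
        res = optimize_dot(q)
        assert res.status == "optimal"
        np.testing.assert_array_equal(res.optimal_profile.values, pure(0).values)
        assert res.damage.value == q.values.max()  # exact, no solver roundoff

    def test_unconstrained_tie_breaks_to_first_canonical(self):
        q = normalize([0, 0.5, 0, 0, 0.5, 0, 0, 0], "c")
        res = optimize_dot(q)
        np.testing.assert_array_equal(res.optimal_profile.values, pure(1).values)

    def test_worked_instance(self, worked_instance):
        q_c, q_h, cap, expected_r, expected_damage = worked_instance
        res = optimize_dot(q_c, [(q_h, cap)])
        assert res.status == "optimal"
        np.testing.assert_allclose(res.optimal_profile.values, expected_r,
                                   atol=1e-8)
        assert res.damage.value == pytest.approx(expected_damage, abs=1e-9)
        assert res.active_constraints == ("healthy",)

    def test_worked_instance_matches_oracle(self, worked_instance):
        q_c, q_h, cap, _, expected_damage = worked_instance
        oracle = brute_force_oracle(q_c, [(q_h, cap)], grid_step=1e-3,
                                    include_slack=False)
        assert oracle.status == "optimal"
        assert abs(oracle.damage.value - expected_damage) <= 1e-3
        lp = optimize_dot(q_c, [(q_h, cap)])
        assert lp.damage.value >= oracle.damage.value - 1e-3

    def test_cap_zero_on_full_support_tissue_infeasible(self):
        q_c = normalize([1] * 8, "c")
        q_h = normalize(np.arange(1.0, 9.0), "h")
        res = optimize_dot(q_c, [(q_h, 0.0)])
        assert res.status == "infeasible"
        assert res.optimal_profile is None
        assert res.message

    def test_solution_feasible_at_tolerance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            q_c, cons = random_instance(rng, support=8, n_constraints=4)
            res = optimize_dot(q_c, cons)
            if res.status != "optimal":
                continue
            r = res.optimal_profile.values
            assert abs(r.sum() - 1) <= 1e-9
            for q_h, cap in cons:
                assert float(q_h.values @ r) <= cap + 1e-7

    def test_negative_cap_rejected(self):
        q = normalize([1] * 8)
        with pytest.raises(ValueError, match="negative cap"):
            optimize_dot(q, [(q, -0.1)])


class TestOracleEquivalence:
    def test_randomized_instances_match_lp(self):
        rng = np.random.default_rng(42)
        for k in range(25):
            support = 3 if k % 2 == 0 else 4
            q_c, cons = random_instance(rng, support)
            step = 1e-2
            # +1 dim for the slack coordinate the oracle adds
            oracle = brute_force_oracle(q_c, cons, grid_step=step,
                                        max_support=support + 1)
            lp = optimize_dot(q_c, cons)
            assert oracle.status == lp.status
            if lp.status == "optimal":
                # two-sided: LP cannot be beaten by, nor beat, the grid by
                # more than the grid resolution
                assert lp.damage.value >= oracle.damage.value - 1e-9
                assert lp.damage.value <= oracle.damage.value + step

    def test_agreement_on_infeasibility(self):
        # a strictly positive tissue with cap 0 rules out every simplex point
        q_c = normalize([1, 1, 1, 0, 0, 0, 0, 0], "c")
        q_h = normalize([1, 1, 1, 1, 1, 1, 1, 1], "h")
        lp = optimize_dot(q_c, [(q_h, 0.0)])
        oracle = brute_force_oracle(q_c, [(q_h, 0.0)], grid_step=0.1,
                                    max_support=8)
        assert lp.status == oracle.status == "infeasible"

    def test_unconstrained_vertex_found_exactly(self):
        q_c = normalize([0.2, 0.7, 0.1, 0, 0, 0, 0, 0], "c")
        oracle = brute_force_oracle(q_c, grid_step=0.05)
        assert oracle.damage.value == pytest.approx(0.7, abs=1e-12)

    def test_support_cap_enforced(self):
        q_c = normalize([1, 1, 1, 1, 1, 0, 0, 0], "c")
        with pytest.raises(ValueError, match="exceed"):
            brute_force_oracle(q_c, grid_step=0.05)

    def test_bad_grid_step(self):
        q_c = normalize([1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="grid_step"):
            brute_force_oracle(q_c, grid_step=0.5)


class TestPenalized:
    def test_zero_penalties_reduce_to_unconstrained(self):
        q = normalize([0.1, 0.2, 0.3, 0.05, 0.05, 0.1, 0.15, 0.05], "c")
        plain = optimize_dot(q)
        pen = optimize_penalized(q, [(normalize([1] * 8, "h"), 0.0)])
        np.testing.assert_array_equal(pen.optimal_profile.values,
                                      plain.optimal_profile.values)
        assert pen.damage.value == plain.damage.value

    def test_net_benefit_argmax(self):
        q_c = normalize([0.6, 0.3, 0.1, 0, 0, 0, 0, 0], "c")
        q_h = normalize([0.8, 0.1, 0.1, 0, 0, 0, 0, 0], "h")
        res = optimize_penalized(q_c, [(q_h, 1.0)])
        # net vector (-0.2, 0.2, 0, ...) -> pure betaIIa, cancer damage 0.3
        np.testing.assert_array_equal(res.optimal_profile.values, pure(1).values)
        assert res.damage.value == pytest.approx(0.3)
        assert res.objective_value == pytest.approx(0.2)

    def test_symmetric_tie_breaks_to_first(self):
        q_c = normalize([0.5, 0.5, 0, 0, 0, 0, 0, 0], "c")
        res = optimize_penalized(q_c)
        np.testing.assert_array_equal(res.optimal_profile.values, pure(0).values)


class TestKl:
    def test_unconstrained_returns_cancer_profile_exactly(self):
        q = normalize([3, 1, 4, 1, 5, 9, 2, 6], "c")
        res = optimize_kl(q)
        assert res.status == "optimal"
        np.testing.assert_array_equal(res.optimal_profile.values, q.values)
        assert res.objective_value == 0.0

    def test_already_feasible_profile_returned_unchanged(self):
        q = normalize([3, 1, 4, 1, 5, 9, 2, 6], "c")
        cons = [(normalize([1] * 8, "h"), 0.5)]
        res = optimize_kl(q, cons)
        np.testing.assert_array_equal(res.optimal_profile.values, q.values)

    def test_boundary_solution_from_kkt(self):
        q_c = normalize([0.5, 0.5, 0, 0, 0, 0, 0, 0], "c")
        res = optimize_kl(q_c, [(pure(0, "h"), 0.2)])
        assert res.status == "optimal"
        np.testing.assert_allclose(res.optimal_profile.values[:2], [0.2, 0.8],
                                   atol=1e-6)
        assert "h" in res.active_constraints

    def test_boundary_solution_matches_grid(self):
        q_c = normalize([0.5, 0.5, 0, 0, 0, 0, 0, 0], "c")
        cons = [(pure(0, "h"), 0.2)]
        oracle = brute_force_oracle(q_c, cons, grid_step=1e-3, model="kl",
                                    include_slack=False)
        res = optimize_kl(q_c, cons)
        assert res.objective_value >= oracle.objective_value - 1e-5

    def test_infeasible_reported(self):
        q_c = normalize([1, 1, 0, 0, 0, 0, 0, 0], "c")
        res = optimize_kl(q_c, [(normalize([1, 1, 0, 0, 0, 0, 0, 0], "h"), 0.0)])
        assert res.status == "infeasible"

    def test_mass_confined_to_cancer_support(self):
        q_c = normalize([0.5, 0.5, 0, 0, 0, 0, 0, 0], "c")
        res = optimize_kl(q_c, [(pure(1, "h"), 0.3)])
        assert res.optimal_profile.values[2:].sum() == 0.0
        assert res.damage.value <= 0.0
        assert res.damage.value > -math.inf


class TestEvaluateDrug:
    def test_optimum_evaluates_to_fraction_one(self, worked_instance):
        q_c, q_h, cap, _, _ = worked_instance
        cons = [(q_h, cap)]
        opt = optimize_dot(q_c, cons)
        ev = evaluate_drug(opt.optimal_profile, q_c, cons, reference=opt)
        assert ev.feasible
        assert ev.fraction_of_optimum == pytest.approx(1.0, abs=1e-9)

    def test_violation_reported_with_numbers(self):
        q_c = normalize([0.6, 0.3, 0.1, 0, 0, 0, 0, 0], "c")
        q_h = normalize([0.8, 0.1, 0.1, 0, 0, 0, 0, 0], "h")
        ev = evaluate_drug(pure(0, "drugA"), q_c, [(q_h, 0.2)])
        assert not ev.feasible
        [(tissue, damage, cap)] = ev.violations
        assert tissue == "h"
        assert damage == pytest.approx(0.8)
        assert cap == 0.2

    def test_vacuous_caps_always_feasible(self):
        rng = np.random.default_rng(3)
        q_c = random_profile(rng, 8, "c")
        cons = [(random_profile(rng, 8, f"h{k}"), 1.0) for k in range(5)]
        for i in range(8):
            assert evaluate_drug(pure(i, f"d{i}"), q_c, cons).feasible

    def test_fraction_zero_when_optimum_zero(self):
        q_c = pure(0, "c")
        opt = optimize_penalized(q_c, [(pure(0, "h"), 2.0)])
        # optimum lands on a zero-expression isotype -> zero cancer damage
        assert opt.damage.value == 0.0
        ev = evaluate_drug(pure(1, "d"), q_c, [], reference=opt)
        assert ev.fraction_of_optimum == 0.0


class TestStructuralProperties:
    def test_cap_scaling_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            q_c, cons = random_instance(rng, support=8, n_constraints=3)
            base = optimize_dot(q_c, cons)
            lam = float(rng.uniform(1.0, 3.0))
            scaled = optimize_dot(q_c, [(q, min(c * lam, 1.0)) for q, c in cons])
            if base.status == "optimal":
                assert scaled.status == "optimal"
                assert scaled.damage.value >= base.damage.value - 1e-9

    def test_adding_constraints_never_increases_damage(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            q_c, cons = random_instance(rng, support=8, n_constraints=3)
            partial = optimize_dot(q_c, cons[:1])
            full = optimize_dot(q_c, cons)
            if full.status == "optimal":
                assert partial.status == "optimal"
                assert full.damage.value <= partial.damage.value + 1e-9

    def test_unconstrained_optimum_is_vertex_with_exact_damage(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            q_c = random_profile(rng, 8, "c")
            res = optimize_dot(q_c)
            r = res.optimal_profile.values
            assert np.count_nonzero(r) == 1
            assert res.damage.value == q_c.values.max()

    def test_result_serialization(self, worked_instance):
        q_c, q_h, cap, _, _ = worked_instance
        doc = optimize_dot(q_c, [(q_h, cap)]).to_dict()
        assert doc["status"] == "optimal"
        assert doc["model"] == "dot"
        assert set(doc["optimal_profile"]["values"]) == {
            "betaI", "betaIIa", "betaIIb", "betaIII",
            "betaIVa", "betaIVb", "betaV", "betaVI"}
        assert doc["active_constraints"] == ["healthy"]
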