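"""Sequential-trialling impact model: pmf, expected months, policies, costs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migrx import (TreatmentCatalog, build_comparator_sequence, compare_policies,
                   cost_delta, evaluate_policy, expected_time_to_response,
                   ite_to_probability, policy_cost, rank_by_ite,
                   sensitivity_strata, success_pmf, topk_coverage)
from migrx.catalog import BOTULINUM_TOXIN
from migrx.studies import homogeneous_policy_check
from tests.conftest import make_cohort

CATALOG = TreatmentCatalog.default()
FLAT = TreatmentCatalog.default(("tca", "topiramate", "betablockers",
                                 "valproate", "candesartan"))  # all 3-month


class TestIteToProbability:
    def test_interior_value_unchanged(self):
        assert ite_to_probability(0.44) == 0.44

    def test_floor_and_ceiling(self):
        assert ite_to_probability(-0.2) == 0.01
        assert ite_to_probability(1.5) == 0.99

    def test_elementwise_on_arrays(self):
        out = ite_to_probability(np.array([-1.0, 0.5, 2.0]))
        assert out.tolist() == [0.01, 0.5, 0.99]


class TestRankByIte:
    def test_descending_order(self):
        assert rank_by_ite({"A": 0.3, "B": 0.1, "C": 0.5}) == ["C", "A", "B"]

    def test_restricted_forces_fourth_position(self):
        ites = {BOTULINUM_TOXIN: 0.9, "A": 0.3, "B": 0.1, "C": 0.5, "D": 0.2}
        assert rank_by_ite(ites, restricted=True) == ["C", "A", "D",
                                                      BOTULINUM_TOXIN, "B"]

    def test_ties_break_alphabetically(self):
        assert rank_by_ite({"B": 0.2, "A": 0.2, "C": 0.1}) == ["A", "B", "C"]

    def test_missing_ite_rejected(self):
        with pytest.raises(ValueError):
            rank_by_ite({"A": np.nan, "B": 0.1})


class TestSuccessPmf:
    def test_certain_first_success(self):
        out = success_pmf([1.0, 0.3])
        assert out.pmf.tolist() == [1.0, 0.0]
        assert out.residual == 0.0

    def test_half_half(self):
        out = success_pmf([0.5, 0.5])
        assert out.pmf.tolist() == [0.5, 0.25]
        assert out.residual == 0.25

    def test_matches_exhaustive_enumeration(self):
        """Enumerate all 2^n success/failure paths and accumulate the first
        success position."""
        rng = np.random.default_rng(0)
        p = rng.random(6)
        out = success_pmf(p)
        pmf = np.zeros(6)
        residual = 0.0
        for path in itertools.product([0, 1], repeat=6):
            prob = np.prod([p[i] if s else 1 - p[i] for i, s in enumerate(path)])
            firsts = [i for i, s in enumerate(path) if s]
            if firsts:
                pmf[firsts[0]] += prob
            else:
                residual += prob
        assert np.allclose(out.pmf, pmf, atol=1e-12)
        assert out.residual == pytest.approx(residual, abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_conservation_property(self, p):
        out = success_pmf(p)
        assert abs(out.pmf.sum() + out.residual - 1.0) < 1e-12

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            success_pmf([0.5, 1.2])


class TestExpectedTime:
    def test_single_certain_treatment(self):
        assert expected_time_to_response(["tca"], [1.0], CATALOG) == 3.0

    def test_hand_enumeration_conditional_and_unconditional(self):
        seq = ["tca", "topiramate"]
        uncond = expected_time_to_response(seq, [0.5, 0.5], CATALOG,
                                           conditional=False)
        cond = expected_time_to_response(seq, [0.5, 0.5], CATALOG)
        assert uncond == pytest.approx(3.0)   # 0.5*3 + 0.25*6
        assert cond == pytest.approx(4.0)     # 3.0 / 0.75

    def test_heterogeneous_durations_accumulate(self):
        # botulinum toxin evaluates over 6 months
        months = expected_time_to_response([BOTULINUM_TOXIN, "tca"],
                                           [0.5, 1.0], CATALOG,
                                           conditional=False)
        assert months == pytest.approx(0.5 * 6 + 0.5 * 9)

    def test_zero_probability_tail_is_noop(self):
        seq = ["tca", "topiramate", "valproate"]
        p = [0.4, 0.3, 0.2]
        base = expected_time_to_response(seq, p, FLAT)
        longer = expected_time_to_response(seq + ["candesartan"], p + [0.0], FLAT)
        assert longer == pytest.approx(base)
        head = success_pmf(p).pmf
        head_longer = success_pmf(p + [0.0]).pmf[:3]
        assert np.allclose(head, head_longer)

    def test_matches_monte_carlo_simulation(self):
        """Closed form vs 1e5 simulated trialling trajectories."""
        rng = np.random.default_rng(1)
        seq = ["tca", "topiramate", "valproate", BOTULINUM_TOXIN]
        p = np.array([0.3, 0.25, 0.2, 0.45])
        t = np.array(CATALOG.durations(seq))
        n = 100_000
        draws = rng.random((n, 4)) < p
        any_success = draws.any(axis=1)
        first = np.argmax(draws, axis=1)
        months = np.cumsum(t)[first][any_success]
        mc = months.mean()
        se = months.std(ddof=1) / np.sqrt(len(months))
        closed = expected_time_to_response(seq, p, CATALOG)
        assert abs(closed - mc) < 3 * se

    def test_descending_order_minimizes_conditional_time(self):
        """Exhaustive check over all 120 permutations of 5 equal-duration
        treatments, 20 random probability vectors."""
        rng = np.random.default_rng(2)
        names = FLAT.names
        for _ in range(20):
            p = dict(zip(names, rng.uniform(0.05, 0.95, 5)))
            best = min(
                expected_time_to_response(list(perm), [p[c] for c in perm], FLAT)
                for perm in itertools.permutations(names)
            )
            seq = rank_by_ite(p)
            ours = expected_time_to_response(seq, [p[c] for c in seq], FLAT)
            assert ours == pytest.approx(best, abs=1e-10)

    def test_all_failures_conditional_undefined(self):
        with pytest.raises(ValueError):
            expected_time_to_response(["tca"], [0.0], CATALOG)


class TestComparatorSequences:
    def test_guideline1_botulinum_always_fourth(self):
        seqs = build_comparator_sequence("guideline1", CATALOG, seed=0,
                                         n_realizations=50)
        for s in seqs:
            assert len(s) == 4 and s[3] == BOTULINUM_TOXIN
            assert len(set(s)) == 4

    def test_guideline2_pool_structure(self):
        seqs = build_comparator_sequence("guideline2", CATALOG, seed=0,
                                         n_realizations=50)
        for s in seqs:
            assert set(s[:2]) <= {"betablockers", "candesartan", "tca", "snri"}
            assert s[2] in {"topiramate", "valproate", "flunarizine"}
            assert s[3] == BOTULINUM_TOXIN

    def test_nice_is_permutation_plus_botulinum(self):
        seqs = build_comparator_sequence("nice", CATALOG, seed=1,
                                         n_realizations=30)
        for s in seqs:
            assert sorted(s[:3]) == ["betablockers", "tca", "topiramate"]
            assert s[3] == BOTULINUM_TOXIN

    def test_cost_ordered_ascending(self):
        (seq,) = build_comparator_sequence("cost_ordered", CATALOG)
        tariffs = [CATALOG.tariff(c, "low") for c in seq]
        assert tariffs == sorted(tariffs)

    def test_random_seeded_and_complete(self):
        a = build_comparator_sequence("random", CATALOG, seed=5, n_realizations=10)
        b = build_comparator_sequence("random", CATALOG, seed=5, n_realizations=10)
        assert a == b
        assert all(sorted(s) == sorted(CATALOG.names) for s in a)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown policy"):
            build_comparator_sequence("hunch", CATALOG)


class TestEvaluateAndCompare:
    def test_homogeneous_probabilities_make_order_irrelevant(self):
        out = homogeneous_policy_check(seed=0)
        assert out["max_abs_diff"] < 1e-9

    def test_same_seed_identical_distribution(self):
        rng = np.random.default_rng(3)
        ites = pd.DataFrame(rng.normal(0.2, 0.1, (30, 5)),
                            columns=FLAT.names,
                            index=pd.Index(range(30), name="patient_id"))
        a = evaluate_policy(ites, "random", FLAT, n_realizations=20, seed=9)
        b = evaluate_policy(ites, "random", FLAT, n_realizations=20, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_compare_identical_vectors(self):
        x = np.array([3.0, 4.5, 6.0, 7.5])
        res = compare_policies(x, x)
        assert res.mean_difference == 0.0

    def test_compare_shifted_vectors(self):
        rng = np.random.default_rng(4)
        a = rng.normal(6, 1, 200)
        res = compare_policies(a, a + 3.75)
        assert res.mean_difference == pytest.approx(-3.75)
        assert res.p_value < 1e-10

    def test_null_comparison_ci_covers_zero(self):
        """Two seeds of the same random policy differ only by Monte-Carlo
        noise."""
        rng = np.random.default_rng(5)
        ites = pd.DataFrame(rng.normal(0.25, 0.15, (100, 5)),
                            columns=FLAT.names,
                            index=pd.Index(range(100), name="patient_id"))
        a = evaluate_policy(ites, "random", FLAT, n_realizations=1000, seed=1)
        b = evaluate_policy(ites, "random", FLAT, n_realizations=1000, seed=2)
        res = compare_policies(a, b)
        assert res.ci_lower < 0 < res.ci_upper


class TestCoverageCostsStrata:
    def test_topk_limits(self):
        rng = np.random.default_rng(6)
        ites = pd.DataFrame(rng.normal(size=(20, 5)), columns=FLAT.names,
                            index=pd.Index(range(20), name="patient_id"))
        trials = pd.DataFrame({"patient_id": list(range(19)),
                               "class_name": ["tca"] * 19})
        assert topk_coverage(ites, trials, 5) == pytest.approx(19 / 20)
        empty_history = topk_coverage(ites, trials.iloc[:0], 1)
        assert empty_history == 0.0

    def test_policy_cost_sums_tariffs(self):
        assert policy_cost(["betablockers", "tca"], 2, CATALOG, "low") == 11.0

    def test_cost_delta_zero_for_identical_sequences(self):
        seq = ["tca", "topiramate"]
        assert cost_delta(seq, seq, 2, CATALOG) == 0.0

    def test_cost_delta_matches_direct_subtraction(self):
        rng = np.random.default_rng(7)
        names = CATALOG.names
        pred = list(rng.permutation(names))
        actual = list(rng.permutation(names))
        n = 4
        direct = (sum(CATALOG.tariff(c, "high") for c in pred[:n])
                  - sum(CATALOG.tariff(c, "high") for c in actual[:n]))
        assert cost_delta(pred, actual, n, CATALOG, "high") == pytest.approx(direct)

    def test_strata_definitions(self):
        cohort = make_cohort([(0, "tca", 1), (1, "tca", 0), (2, "tca", 1)])
        cohort.patients["headache_days"] = [26, 20, 26]
        cohort.patients["exacerbation_intensity"] = [9, 7, 7]
        severe, less = sensitivity_strata(cohort)
        assert severe.tolist() == [True, False, False]
        assert less.tolist() == [False, True, False]
        # (26, 7) matches neither conjunction
        assert not severe.iloc[2] and not less.iloc[2]
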