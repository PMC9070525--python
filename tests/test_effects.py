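"""ITE aggregation, subgroup rules, the paired contrast and CV validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from migrx import (aggregate_class_ite, conditional_subgroup,
                   cv_validation_accuracy, describe_distribution,
                   load_reference_effects, paired_difference_test,
                   reference_rate_vectors, summarize_effects)
from tests.conftest import make_cohort


def _series(values, ids=None):
    ids = ids if ids is not None else range(len(values))
    return pd.Series(values, index=pd.Index(ids, name="patient_id"))


class TestAggregateClassITE:
    def test_mean_of_signed_pairwise_effects(self):
        pairwise = {("A", "B"): _series([0.2]), ("A", "C"): _series([0.4]),
                    ("B", "C"): _series([0.1])}
        ites = aggregate_class_ite(pairwise, classes=["A", "B", "C"])
        assert ites.loc[0, "A"] == pytest.approx(0.3)

    def test_sign_flips_for_second_named_class(self):
        # tau stored B-signed as -0.2 contributes +0.2 to A
        pairwise = {("B", "A"): _series([-0.2]), ("A", "C"): _series([0.4]),
                    ("B", "C"): _series([0.0])}
        ites = aggregate_class_ite(pairwise, classes=["A", "B", "C"])
        assert ites.loc[0, "A"] == pytest.approx((0.2 + 0.4) / 2)

    def test_ten_classes_need_45_pairs_with_9_terms_each(self):
        classes = [f"c{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        pairwise = {(a, b): _series(rng.normal(size=3))
                    for a, b in itertools.combinations(classes, 2)}
        assert len(pairwise) == 45
        ites = aggregate_class_ite(pairwise, classes=classes)
        c = classes[4]
        manual = sum(
            (s if a == c else -s)
            for (a, b), s in pairwise.items() if c in (a, b)
        ) / 9.0
        assert np.allclose(ites[c], manual)

    def test_missing_pair_marks_class_undefined(self):
        # a class's ITE requires every pair involving it: with C's pairs
        # absent, C is undefined everywhere — and so is A, which lacks (A, C)
        pairwise = {("A", "B"): _series([0.2])}
        ites = aggregate_class_ite(pairwise, classes=["A", "B", "C"])
        assert ites.isna().all().all()
        two_class = aggregate_class_ite(pairwise, classes=["A", "B"])
        assert two_class.notna().all().all()
        assert two_class.loc[0, "A"] == pytest.approx(0.2)
        assert two_class.loc[0, "B"] == pytest.approx(-0.2)


class TestConditionalSubgroup:
    def test_strictly_above_median(self):
        mask = conditional_subgroup(_series([0.1, 0.2, 0.3]))
        assert mask.tolist() == [False, False, True]

    def test_all_equal_gives_empty_subgroup(self):
        assert not conditional_subgroup(_series([0.2, 0.2, 0.2])).any()

    def test_even_sized_distinct_values_upper_half(self):
        mask = conditional_subgroup(_series([0.1, 0.2, 0.3, 0.4]))
        assert mask.tolist() == [False, False, True, True]


class TestSummarizeEffects:
    def test_median_and_iqr_order_statistics(self):
        ites = pd.DataFrame({"tca": [0.1, 0.2, 0.3, 0.4]},
                            index=pd.Index(range(4), name="patient_id"))
        cohort = make_cohort([(0, "tca", 1), (1, "tca", 0),
                              (2, "tca", 1), (3, "tca", 1)])
        summ = summarize_effects(ites, cohort)
        row = summ.loc["tca"]
        assert row["ate_median"] == pytest.approx(0.25)
        assert (row["ate_q1"], row["ate_q3"]) == pytest.approx((0.175, 0.325))

    def test_true_rates_equal_brute_force_counts(self):
        rng = np.random.default_rng(5)
        spec = [(pid, "tca", int(rng.random() < 0.4)) for pid in range(40)]
        cohort = make_cohort(spec)
        ites = pd.DataFrame({"tca": rng.normal(size=40)},
                            index=pd.Index(range(40), name="patient_id"))
        summ = summarize_effects(ites, cohort)
        responses = {pid: r for pid, _, r in spec}
        overall = np.mean([responses[p] for p in range(40)])
        med = np.median(ites["tca"])
        cond_ids = [p for p in range(40) if ites.loc[p, "tca"] > med]
        conditional = np.mean([responses[p] for p in cond_ids])
        assert summ.loc["tca", "overall_true"] == pytest.approx(overall)
        assert summ.loc["tca", "conditional_true"] == pytest.approx(conditional)

    def test_untrialled_class_flagged(self):
        cohort = make_cohort([(0, "tca", 1), (1, "tca", 0), (2, "tca", 1)])
        ites = pd.DataFrame({"tca": [0.1, 0.2, 0.3], "snri": [0.3, 0.2, 0.1]},
                            index=pd.Index(range(3), name="patient_id"))
        with pytest.warns(UserWarning, match="snri"):
            summ = summarize_effects(ites, cohort)
        assert not summ.loc["snri", "true_rates_defined"]
        assert np.isnan(summ.loc["snri", "overall_true"])


class TestPairedDifferenceTest:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_difference_test([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])

    def test_type_i_error_calibrated(self):
        """Null differences N(0, 0.05^2), k=10: rejection rate ~ alpha."""
        rng = np.random.default_rng(0)
        k, reps = 10, 10_000
        d = rng.normal(0.0, 0.05, size=(reps, k))
        t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(k))
        p = 2 * stats.t.sf(np.abs(t), k - 1)
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06
        # spot-check agreement with the implementation on a few draws
        for row in d[:5]:
            res = paired_difference_test(np.zeros(k), row)
            ref = 2 * stats.t.sf(abs(row.mean() / (row.std(ddof=1) / np.sqrt(k))), k - 1)
            assert res.p_value == pytest.approx(ref)

    def test_ci_agrees_with_bootstrap_on_reference_table(self):
        overall, conditional = reference_rate_vectors()
        res = paired_difference_test(overall, conditional)
        rng = np.random.default_rng(1)
        d = conditional - overall
        idx = rng.integers(0, len(d), size=(10_000, len(d)))
        boots = d[idx].mean(axis=1)
        lo, hi = np.quantile(boots, [0.025, 0.975])
        assert abs(lo - res.ci_lower) < 0.01
        assert abs(hi - res.ci_upper) < 0.01


class TestCVValidationAccuracy:
    def test_perfect_separation_gives_unit_accuracy(self):
        ites = np.concatenate([np.linspace(1, 2, 30), np.linspace(-2, -1, 30)])
        resp = np.array([1] * 30 + [0] * 30)
        acc, sd = cv_validation_accuracy(ites, resp, folds=10, seed=0)
        assert acc == 1.0

    def test_constant_predictor_falls_back_to_majority(self):
        rng = np.random.default_rng(2)
        resp = (rng.random(200) < 0.6).astype(int)
        acc, _ = cv_validation_accuracy(np.zeros(200), resp, folds=10, seed=0)
        assert acc == pytest.approx(resp.mean(), abs=0.05)

    def test_informative_ites_beat_chance(self):
        rng = np.random.default_rng(3)
        ites = rng.normal(size=400)
        resp = (rng.random(400) < expit(2.0 * ites)).astype(int)
        acc, sd = cv_validation_accuracy(ites, resp, folds=10, seed=0)
        assert acc > 0.5 + 2 * sd

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            cv_validation_accuracy(np.ones(20), np.ones(20, int))


class TestReportingHelpers:
    def test_normal_sample_reported_as_mean_sd(self):
        x = np.random.default_rng(4).normal(10, 2, 200)
        out = describe_distribution(x)
        assert out["labels"] == ("mean", "sd")

    def test_skewed_sample_reported_as_median_iqr(self):
        x = np.random.default_rng(5).lognormal(0, 1.5, 200)
        out = describe_distribution(x)
        assert out["labels"] == ("median", "iqr")

    def test_reference_table_shape_and_rows(self):
        df = load_reference_effects()
        assert len(df) == 10
        assert df.loc["botulinum_toxin", ["overall_true", "conditional_true"]].tolist() == [0.47, 0.51]
        assert df.loc["flunarizine", ["overall_true", "conditional_true"]].tolist() == [0.64, 0.76]
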