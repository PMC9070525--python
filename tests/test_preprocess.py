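"""Stratified splitting and PPCA imputation."""

import numpy as np
import pandas as pd
import pytest

from migrx import (PPCAImputer, SplitSpec, SyntheticConfig, apply_imputer,
                   fit_imputer, generate_cohort, inject_missingness,
                   stratified_split)


@pytest.fixture(scope="module")
def cohort_1000():
    cfg = SyntheticConfig(n_patients=1000,
                          classes=("tca", "topiramate", "betablockers"),
                          seed=21)
    return generate_cohort(cfg)[0]


class TestStratifiedSplit:
    def test_sizes_follow_stated_ratios(self, cohort_1000):
        train, val, test = stratified_split(cohort_1000, SplitSpec(seed=1))
        assert (train.n_patients, val.n_patients, test.n_patients) == (640, 160, 200)

    def test_partitions_disjoint_and_exhaustive(self, cohort_1000):
        train, val, test = stratified_split(cohort_1000, SplitSpec(seed=1))
        ids = [set(p.patient_ids) for p in (train, val, test)]
        assert ids[0] | ids[1] | ids[2] == set(cohort_1000.patient_ids)
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])

    def test_same_seed_same_partition(self, cohort_1000):
        a = stratified_split(cohort_1000, SplitSpec(seed=3))
        b = stratified_split(cohort_1000, SplitSpec(seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x.patient_ids, y.patient_ids)

    def test_stratification_preserves_prevalence(self, cohort_1000):
        train, val, test = stratified_split(cohort_1000, SplitSpec(seed=2))
        overall = (cohort_1000.trials.groupby("patient_id")["response"].max()
                   .reindex(cohort_1000.patients.index, fill_value=0).mean())
        for part in (train, val, test):
            prev = (part.trials.groupby("patient_id")["response"].max()
                    .reindex(part.patients.index, fill_value=0).mean())
            assert abs(prev - overall) < 0.02

    def test_tiny_stratum_falls_back_with_warning(self, cohort_1000):
        spec = SplitSpec(strat_keys=("headache_days",), seed=0)
        with pytest.warns(UserWarning, match="too small"):
            train, val, test = stratified_split(cohort_1000, spec)
        assert train.n_patients + val.n_patients + test.n_patients == 1000


class TestPPCAImputer:
    def _rank1(self, n=200, d=40, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(n)
        v = rng.uniform(0.5, 1.5, d) * rng.choice([-1, 1], d)
        X = np.outer(u, v) + noise * rng.standard_normal((n, d))
        return pd.DataFrame(X, columns=[f"x{j:02d}" for j in range(d)])

    def test_rank1_missing_cells_recovered(self):
        """Low-rank structure lets PPCA reconstruct masked cells accurately."""
        truth = self._rank1()
        rng = np.random.default_rng(1)
        mask = rng.random(truth.shape) < 0.05
        observed = truth.mask(mask)
        imp = PPCAImputer(n_components=1, seed=0).fit(observed)
        filled = imp.impute(observed)
        rmse = np.sqrt(np.mean((filled.to_numpy()[mask] - truth.to_numpy()[mask]) ** 2))
        assert rmse < 0.05

    def test_complete_table_observed_values_unchanged(self):
        truth = self._rank1(n=80, d=10)
        imp = PPCAImputer(n_components=2, seed=0).fit(truth)
        filled = imp.impute(truth)
        assert np.allclose(filled.to_numpy(), truth.to_numpy(), atol=1e-8)

    def test_em_loglik_trace_non_decreasing(self):
        truth = self._rank1(n=120, d=15, noise=0.3, seed=2)
        observed = truth.mask(np.random.default_rng(3).random(truth.shape) < 0.08)
        imp = PPCAImputer(n_components=3, seed=0).fit(observed)
        diffs = np.diff(imp.loglik_trace_)
        assert (diffs >= -1e-6).all()

    def test_all_missing_column_raises_with_name(self):
        truth = self._rank1(n=30, d=5)
        truth["x02"] = np.nan
        with pytest.raises(ValueError, match="x02"):
            PPCAImputer(n_components=1).fit(truth)

    def test_n_components_must_be_below_feature_count(self):
        with pytest.raises(ValueError):
            PPCAImputer(n_components=5).fit(self._rank1(n=30, d=5))


@pytest.fixture(scope="module")
def fitted(cohort_1000):
    cohort = inject_missingness(cohort_1000, 0.05, seed=4)
    train, val, test = stratified_split(cohort, SplitSpec(seed=5))
    return train, test, fit_imputer(train, n_components=8, seed=0)


class TestApplyImputer:

    def test_training_continuous_standardized(self, fitted):
        train, _, imp = fitted
        out = apply_imputer(imp, train)
        cont = [c for c in out.feature_columns if c not in out.binary_columns]
        X = out.patients[cont]
        # small departures from exactly 0/1 stem from imputed cells only
        assert X.mean().abs().max() < 0.05
        assert (X.std(ddof=0) - 1).abs().max() < 0.05

    def test_binary_columns_stay_binary(self, fitted):
        train, _, imp = fitted
        out = apply_imputer(imp, train)
        vals = np.unique(out.patients[out.binary_columns].to_numpy())
        assert set(vals) <= {0.0, 1.0}

    def test_no_missing_cells_remain(self, fitted):
        _, test, imp = fitted
        out = apply_imputer(imp, test)
        assert not out.patients[out.feature_columns].isna().any().any()

    def test_test_scaled_with_training_statistics(self, fitted):
        """Leakage guard: shifting the test distribution must show up in the
        transformed values (they are not re-centered on the test set)."""
        _, test, imp = fitted
        shifted = test.patients[test.feature_columns].copy()
        cont = [c for c in test.feature_columns if c not in test.binary_columns]
        shifted[cont] = shifted[cont] + 5.0
        out = imp.transform(shifted)
        assert out[cont].mean().min() > 2.0

    def test_transform_rowwise_independent(self, fitted):
        """Each row's transform depends only on that row and the fitted
        training model, so subsetting commutes with transforming."""
        _, test, imp = fitted
        full = imp.transform(test.patients[test.feature_columns])
        subset = imp.transform(test.patients[test.feature_columns].iloc[:10])
        pd.testing.assert_frame_equal(full.iloc[:10], subset)

    def test_unseen_column_rejected(self, fitted):
        _, test, imp = fitted
        bad = test.patients[test.feature_columns].copy()
        bad["zz_new"] = 1.0
        with pytest.raises(ValueError, match="zz_new"):
            imp.transform(bad)
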