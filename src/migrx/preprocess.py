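"""Stratified splitting, probabilistic-PCA imputation and feature scaling.

The analysis partitions the cohort 4:1 into (training+validation) : test, and
the training side again 4:1 into training : validation, stratified so that
outcome balance is preserved.  Missing feature cells are imputed with a
probabilistic PCA model fitted by expectation-maximisation *on the training
partition only*; continuous features are then standardized with training
statistics and binary features are thresholded back to {0, 1}.  No statistic
of the validation or test partitions ever enters the imputer or the scaler.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import CohortTable

__all__ = ["SplitSpec", "stratified_split", "PPCAImputer", "fit_imputer", "apply_imputer"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Ratios and stratification keys for the three-way split.

    ``train_test_ratio`` is (train+validation):test, ``train_val_ratio`` is
    train:validation within the non-test side; the defaults give the
    16 : 4 : 5 partition (64% / 16% / 20%).  Default stratification keys are a
    binned count of trialled classes and an any-response indicator.
    """

    train_test_ratio: float = 4.0
    train_val_ratio: float = 4.0
    strat_keys: tuple[str, ...] = ("n_trials_bin", "any_response")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_test_ratio <= 0 or self.train_val_ratio <= 0:
            raise ValueError("split ratios must be positive")

    @property
    def test_fraction(self) -> float:
        return 1.0 / (1.0 + self.train_test_ratio)

    @property
    def val_fraction_within_trainval(self) -> float:
        return 1.0 / (1.0 + self.train_val_ratio)


def _stratum_labels(cohort: CohortTable, keys: Sequence[str]) -> pd.Series:
    """Derive the stratification label per patient."""
    parts = []
    counts = cohort.trials.groupby("patient_id").size()
    any_resp = cohort.trials.groupby("patient_id")["response"].max()
    for key in keys:
        if key == "n_trials_bin":
            n_trials = counts.reindex(cohort.patients.index, fill_value=0)
            parts.append(pd.cut(n_trials, bins=[-1, 1, 3, 6, np.inf],
                                labels=["0-1", "2-3", "4-6", "7+"]).astype(str))
        elif key == "any_response":
            parts.append(any_resp.reindex(cohort.patients.index, fill_value=0).astype(str))
        elif key in cohort.patients.columns:
            parts.append(cohort.patients[key].astype(str))
        else:
            raise KeyError(f"unknown stratification key {key!r}")
    label = parts[0]
    for p in parts[1:]:
        label = label.str.cat(p, sep="|")
    return label


def _largest_remainder(ideal: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total``, proportional to ``ideal``."""
    base = np.floor(ideal).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(ideal - base))
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(ideal - base)
        take = 0
        for i in order:
            if take == -short:
                break
            if base[i] > 0:
                base[i] -= 1
                take += 1
    return base


def stratified_split(
    cohort: CohortTable, spec: SplitSpec | None = None
) -> tuple[CohortTable, CohortTable, CohortTable]:
    """Split into (train, validation, test), stratified and seeded.

    Partition sizes follow the spec ratios exactly at the cohort level
    (largest-remainder rounding across strata).  Strata smaller than three
    patients cannot be split three ways and fall back, with a warning, to a
    pooled unstratified remainder.
    """
    spec = spec or SplitSpec()
    labels = _stratum_labels(cohort, spec.strat_keys)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))

    n = cohort.n_patients
    n_test = int(round(n * spec.test_fraction))
    n_val = int(round((n - n_test) * spec.val_fraction_within_trainval))

    strata: list[np.ndarray] = []
    pooled: list[np.ndarray] = []
    for _, idx in sorted(labels.groupby(labels).groups.items()):
        ids = idx.to_numpy()
        if len(ids) < 3:
            warnings.warn(
                f"stratum of size {len(ids)} too small to stratify; pooling",
                UserWarning, stacklevel=2,
            )
            pooled.append(ids)
        else:
            strata.append(ids)
    if pooled:
        strata.append(np.concatenate(pooled))

    sizes = np.array([len(s) for s in strata], dtype=float)
    test_counts = _largest_remainder(sizes * n_test / n, n_test)
    remaining = sizes - test_counts
    val_counts = _largest_remainder(remaining * n_val / remaining.sum(), n_val)

    test_ids, val_ids, train_ids = [], [], []
    for ids, t_s, v_s in zip(strata, test_counts, val_counts):
        perm = rng.permutation(ids)
        test_ids.append(perm[:t_s])
        val_ids.append(perm[t_s:t_s + v_s])
        train_ids.append(perm[t_s + v_s:])

    def _take(chunks):
        ids = np.concatenate(chunks)
        return cohort.subset(np.sort(ids))

    train, val, test = _take(train_ids), _take(val_ids), _take(test_ids)
    logger.info("stratified_split: train=%d val=%d test=%d",
                train.n_patients, val.n_patients, test.n_patients)
    return train, val, test


def partition_frame(train: CohortTable, val: CohortTable, test: CohortTable) -> pd.DataFrame:
    """Long partition-assignment table (patient_id, partition)."""
    rows = []
    for name, part in (("train", train), ("validation", val), ("test", test)):
        rows.append(pd.DataFrame({"patient_id": part.patient_ids, "partition": name}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Probabilistic PCA imputation
# ---------------------------------------------------------------------------

class PPCAImputer:
    """Probabilistic PCA imputer fitted by EM with missing data.

    The model is ``x = mu + W z + eps`` with ``z ~ N(0, I_q)`` and isotropic
    residual ``eps ~ N(0, sigma^2 I)``, fitted on internally standardized
    features by exact EM over both the latent factors and the missing cells,
    so the observed-data log-likelihood is non-decreasing across iterations.
    Transforming fills missing cells with their posterior mean; continuous
    columns are returned standardized by the *training* statistics and binary
    columns are thresholded back to {0, 1} at 0.5 on the original scale.
    """

    def __init__(self, n_components: int = 10, max_iter: int = 500,
                 tol: float = 1e-6, seed: int = 0):
        if n_components < 1:
            raise ValueError("n_components must be positive")
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.feature_columns: list[str] | None = None
        self.binary_columns: list[str] = []

    # -- fitting -------------------------------------------------------------
    def fit(self, features: pd.DataFrame, binary_columns: Sequence[str] = ()) -> "PPCAImputer":
        if features.empty:
            raise ValueError("training table is empty")
        if self.n_components >= features.shape[1]:
            raise ValueError("n_components must be smaller than the feature count")
        self.feature_columns = list(features.columns)
        self.binary_columns = [c for c in binary_columns if c in features.columns]

        X = features.to_numpy(dtype=float)
        obs = ~np.isnan(X)
        all_missing = ~obs.any(axis=0)
        if all_missing.any():
            bad = [self.feature_columns[j] for j in np.flatnonzero(all_missing)]
            raise ValueError(f"feature column(s) entirely missing: {bad}")

        self.mean_raw_ = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.scale_raw_ = sd

        Z = (X - self.mean_raw_) / self.scale_raw_
        self.W_, self.sigma2_, self.mu_, self.loglik_trace_ = self._em(Z, obs)
        return self

    def _em(self, Z: np.ndarray, obs: np.ndarray):
        n, d = Z.shape
        q = self.n_components
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 3]))
        W = 0.1 * rng.standard_normal((d, q))
        mu = np.zeros(d)
        sigma2 = 1.0
        trace: list[float] = []

        for _ in range(self.max_iter):
            ll = self._observed_loglik(Z, obs, W, mu, sigma2)
            trace.append(ll)
            if len(trace) > 1:
                rel = (trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
                if 0 <= rel < self.tol:
                    break

            # E-step (per row, observed subset o)
            S_xz = np.zeros((d, q + 1))       # sum_i E[x_i ztilde_i^T]
            S_zz = np.zeros((q + 1, q + 1))   # sum_i E[ztilde ztilde^T]
            S_x2 = 0.0                        # sum_i E[||x_i||^2]
            Ex_all = np.zeros((n, d))
            Covtrace = 0.0                    # sum_i tr(W Cov_i W^T) pieces handled below
            Mz = np.zeros((n, q))
            Sig_list = []
            for i in range(n):
                o = obs[i]
                Wo = W[o]
                r = Z[i, o] - mu[o]
                M = sigma2 * np.eye(q) + Wo.T @ Wo
                Minv = np.linalg.inv(M)
                m_z = Minv @ (Wo.T @ r)
                Sig_z = sigma2 * Minv
                Mz[i] = m_z
                Sig_list.append(Sig_z)
                ex = np.where(o, Z[i], mu + W @ m_z)
                Ex_all[i] = ex

            for i in range(n):
                o = obs[i]
                m = ~o
                m_z = Mz[i]
                Sig_z = Sig_list[i]
                Ezz = Sig_z + np.outer(m_z, m_z)
                ex = Ex_all[i]
                # E[x ztilde^T]
                Exz = np.outer(ex, m_z)
                if m.any():
                    Exz[m] += W[m] @ Sig_z
                S_xz[:, :q] += Exz
                S_xz[:, q] += ex
                S_zz[:q, :q] += Ezz
                S_zz[:q, q] += m_z
                S_zz[q, :q] += m_z
                S_zz[q, q] += 1.0
                # E[||x||^2]: observed entries exact, missing add variance
                S_x2 += float(ex @ ex)
                if m.any():
                    Wm = W[m]
                    S_x2 += m.sum() * sigma2 + float(np.sum((Wm @ Sig_z) * Wm))

            # M-step: joint update of [W mu] then sigma^2
            Wt = np.linalg.solve(S_zz + 1e-12 * np.eye(q + 1), S_xz.T).T
            W_new, mu_new = Wt[:, :q], Wt[:, q]
            # sigma^2 from expected residual
            cross = float(np.sum(Wt * S_xz))
            quad = float(np.sum((Wt @ S_zz) * Wt))
            sigma2_new = max((S_x2 - 2 * cross + quad) / (n * d), 1e-10)
            W, mu, sigma2 = W_new, mu_new, sigma2_new

        return W, sigma2, mu, trace

    @staticmethod
    def _observed_loglik(Z, obs, W, mu, sigma2) -> float:
        n, d = Z.shape
        q = W.shape[1]
        total = 0.0
        for i in range(n):
            o = obs[i]
            do = int(o.sum())
            Wo = W[o]
            r = Z[i, o] - mu[o]
            M = sigma2 * np.eye(q) + Wo.T @ Wo
            sign, logdetM = np.linalg.slogdet(M)
            logdet = (do - q) * np.log(sigma2) + logdetM
            alpha = np.linalg.solve(M, Wo.T @ r)
            quad = (r @ r - r @ (Wo @ alpha)) / sigma2
            total += -0.5 * (do * np.log(2 * np.pi) + logdet + quad)
        return total

    # -- transforming --------------------------------------------------------
    def _check_columns(self, features: pd.DataFrame) -> None:
        if self.feature_columns is None:
            raise RuntimeError("imputer is not fitted")
        unseen = set(features.columns) - set(self.feature_columns)
        if unseen:
            raise ValueError(f"unseen feature column(s): {sorted(unseen)}")
        missing = set(self.feature_columns) - set(features.columns)
        if missing:
            raise ValueError(f"missing feature column(s): {sorted(missing)}")

    def impute(self, features: pd.DataFrame) -> pd.DataFrame:
        """Fill missing cells with posterior means, on the original scale."""
        self._check_columns(features)
        features = features[self.feature_columns]
        X = features.to_numpy(dtype=float)
        obs = ~np.isnan(X)
        Z = (X - self.mean_raw_) / self.scale_raw_
        q = self.n_components
        out = Z.copy()
        for i in range(len(Z)):
            o = obs[i]
            if o.all():
                continue
            Wo = self.W_[o]
            r = Z[i, o] - self.mu_[o]
            M = self.sigma2_ * np.eye(q) + Wo.T @ Wo
            m_z = np.linalg.solve(M, Wo.T @ r)
            m = ~o
            out[i, m] = self.mu_[m] + self.W_[m] @ m_z
        raw = out * self.scale_raw_ + self.mean_raw_
        return pd.DataFrame(raw, index=features.index, columns=self.feature_columns)

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        """Impute then scale: continuous columns standardized by training
        statistics, binary columns thresholded at 0.5 on the original scale."""
        raw = self.impute(features)
        out = (raw - self.mean_raw_) / self.scale_raw_
        for c in self.binary_columns:
            out[c] = (raw[c] > 0.5).astype(float)
        return out

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "feature_columns": self.feature_columns,
            "binary_columns": self.binary_columns,
            "mean_raw": self.mean_raw_.tolist(),
            "scale_raw": self.scale_raw_.tolist(),
            "mu": self.mu_.tolist(),
            "W": self.W_.tolist(),
            "sigma2": self.sigma2_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PPCAImputer":
        imp = cls(n_components=d["n_components"])
        imp.feature_columns = list(d["feature_columns"])
        imp.binary_columns = list(d["binary_columns"])
        imp.mean_raw_ = np.asarray(d["mean_raw"], dtype=float)
        imp.scale_raw_ = np.asarray(d["scale_raw"], dtype=float)
        imp.mu_ = np.asarray(d["mu"], dtype=float)
        imp.W_ = np.asarray(d["W"], dtype=float)
        imp.sigma2_ = float(d["sigma2"])
        imp.loglik_trace_ = []
        return imp


def fit_imputer(train: CohortTable, n_components: int = 10, seed: int = 0,
                **kwargs) -> PPCAImputer:
    """Fit the PPCA imputer on the training partition's feature columns."""
    features = train.patients[train.feature_columns]
    return PPCAImputer(n_components=n_components, seed=seed, **kwargs).fit(
        features, binary_columns=train.binary_columns
    )


def apply_imputer(model: PPCAImputer, cohort: CohortTable) -> CohortTable:
    """Return a cohort whose features are imputed and scaled by ``model``."""
    transformed = model.transform(cohort.patients[cohort.feature_columns])
    return cohort.with_features(transformed)
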