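"""Pairwise individualized-treatment-effect estimation.

For every ordered pair of preventative classes (A, B), patients who trialled
either class form a two-arm observational dataset (arm 1 = A, arm 0 = B; a
patient who trialled both contributes one row per arm).  A causal multitask
GP (:mod:`migrx.gp`) is fitted to the two potential-outcome surfaces, and the
posterior-mean difference tau(x) = m_A(x) - m_B(x) is the pairwise
individualized treatment effect, predicted for *every* patient of a partition
whether or not they trialled either class.  Kernel hyperparameter families
are selected on validation data by discounted cumulative gain (DCG) of the
observed responses ranked by predicted effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gp import KernelConfig, MultitaskGP
from .synthetic import CohortTable

__all__ = [
    "PairDataset",
    "CMGPModel",
    "PairwiseEffects",
    "assemble_pair_dataset",
    "fit_cmgp",
    "predict_pair_ite",
    "dcg_score",
    "select_kernel",
]

#: Default minimum rows per arm before a pair model is considered fittable,
#: in the spirit of the source cohort's at-least-100-trials inclusion rule.
MIN_ROWS_PER_ARM = 20


@dataclass
class PairDataset:
    """Two-arm dataset for one treatment pair (arm 1 = ``class_a``)."""

    X: np.ndarray
    w: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray
    class_a: str
    class_b: str
    feature_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.w) == len(self.y) == len(self.patient_ids)):
            raise ValueError("PairDataset fields must be aligned")

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(self.X[idx], self.w[idx], self.y[idx],
                           self.patient_ids[idx], self.class_a, self.class_b,
                           list(self.feature_columns))


@dataclass
class PairwiseEffects:
    """Predicted pairwise effects, signed toward ``class_a``."""

    patient_ids: np.ndarray
    tau: np.ndarray
    m_a: np.ndarray
    m_b: np.ndarray
    class_a: str
    class_b: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.tau, index=pd.Index(self.patient_ids, name="patient_id"),
                         name=f"{self.class_a}_vs_{self.class_b}")


@dataclass
class CMGPModel:
    """A fitted pair model with its kernel config and optimum diagnostics."""

    gp: MultitaskGP
    kernel_config: KernelConfig
    class_a: str
    class_b: str
    log_marginal_likelihood: float
    feature_columns: list[str] = field(default_factory=list)


def assemble_pair_dataset(
    cohort: CohortTable,
    class_a: str,
    class_b: str,
    min_rows_per_arm: int = MIN_ROWS_PER_ARM,
) -> PairDataset:
    """Rows for every trial of ``class_a`` (arm 1) or ``class_b`` (arm 0).

    Features must be complete (imputed) before assembly.  Raises when either
    arm has fewer than ``min_rows_per_arm`` rows.
    """
    if class_a == class_b:
        raise ValueError("the two classes of a pair must differ")
    Xs, ws, ys, ids = [], [], [], []
    for arm, cname in ((1, class_a), (0, class_b)):
        resp = cohort.responses(cname)
        if resp.index.duplicated().any():
            resp = resp[~resp.index.duplicated(keep="first")]
        pid = resp.index.to_numpy()
        Xs.append(cohort.feature_matrix(pid))
        ws.append(np.full(len(pid), arm, dtype=int))
        ys.append(resp.to_numpy(dtype=float))
        ids.append(pid)
    X = np.vstack(Xs)
    if np.isnan(X).any():
        raise ValueError("pair dataset features contain missing values; impute first")
    w = np.concatenate(ws)
    y = np.concatenate(ys)
    pid = np.concatenate(ids)
    for arm, cname in ((1, class_a), (0, class_b)):
        n_arm = int((w == arm).sum())
        if n_arm < min_rows_per_arm:
            raise ValueError(
                f"arm {cname!r} has only {n_arm} rows "
                f"(minimum {min_rows_per_arm})"
            )
    return PairDataset(X, w, y, pid, class_a, class_b, list(cohort.feature_columns))


def fit_cmgp(
    train: PairDataset,
    kconf: KernelConfig | None = None,
    seed: int = 0,
    n_restarts: int | None = None,
) -> CMGPModel:
    """Fit the multitask GP to a pair dataset by multi-restart L-BFGS."""
    kconf = kconf or KernelConfig()
    gp = MultitaskGP(kconf).fit(train.X, train.w, train.y, seed=seed,
                                n_restarts=n_restarts)
    return CMGPModel(
        gp=gp,
        kernel_config=kconf,
        class_a=train.class_a,
        class_b=train.class_b,
        log_marginal_likelihood=gp.log_marginal_likelihood_,
        feature_columns=list(train.feature_columns),
    )


def predict_pair_ite(
    model: CMGPModel,
    features: np.ndarray | pd.DataFrame | CohortTable,
    patient_ids: Sequence | None = None,
) -> PairwiseEffects:
    """Posterior-mean pairwise effect for every row of ``features``.

    Accepts a raw matrix, a feature DataFrame, or a cohort (whose patients all
    receive a prediction, trialled or not).
    """
    if isinstance(features, CohortTable):
        patient_ids = features.patient_ids
        X = features.feature_matrix()
    elif isinstance(features, pd.DataFrame):
        patient_ids = features.index.to_numpy() if patient_ids is None else np.asarray(patient_ids)
        X = features.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        patient_ids = (np.arange(len(X)) if patient_ids is None
                       else np.asarray(patient_ids))
    m_b, m_a = model.gp.predict_surfaces(X)  # arm 0 = B, arm 1 = A
    return PairwiseEffects(
        patient_ids=np.asarray(patient_ids),
        tau=m_a - m_b,
        m_a=m_a,
        m_b=m_b,
        class_a=model.class_a,
        class_b=model.class_b,
    )


def dcg_score(predicted_effects: np.ndarray, observed_responses: np.ndarray) -> float:
    """Discounted cumulative gain of observed responses ranked by prediction.

    Patients are sorted by predicted effect descending (ties broken stably);
    DCG = sum_i rel_i / log2(i + 1) with 1-based rank i and rel = the
    observed binary response.
    """
    pred = np.asarray(predicted_effects, dtype=float)
    rel = np.asarray(observed_responses, dtype=float)
    if pred.shape != rel.shape or pred.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(pred) == 0:
        raise ValueError("dcg_score requires at least one observation")
    order = np.argsort(-pred, kind="stable")
    ranks = np.arange(1, len(pred) + 1)
    return float(np.sum(rel[order] / np.log2(ranks + 1)))


def _validation_dcg(model: CMGPModel, validation: PairDataset) -> float:
    """Sum of per-arm DCGs on the validation pair data.

    Arm A patients are ranked by tau, arm B patients by -tau (the effect
    signed toward the arm whose response was observed).
    """
    effects = predict_pair_ite(model, validation.X)
    total = 0.0
    for arm, sign in ((1, 1.0), (0, -1.0)):
        mask = validation.w == arm
        if mask.any():
            total += dcg_score(sign * effects.tau[mask], validation.y[mask])
    return total


def select_kernel(
    train: PairDataset,
    validation: PairDataset,
    candidates: Sequence[KernelConfig],
    seed: int = 0,
) -> KernelConfig:
    """Pick the candidate whose fitted model maximizes validation DCG.

    Ties are broken by list order (the first maximizer wins).
    """
    if len(candidates) == 0:
        raise ValueError("need at least one kernel candidate")
    if len(candidates) == 1:
        return candidates[0]
    best_conf, best_score = None, -np.inf
    for conf in candidates:
        model = fit_cmgp(train, conf, seed=seed)
        score = _validation_dcg(model, validation)
        if score > best_score:
            best_conf, best_score = conf, score
    return best_conf
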