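"""Synthetic chronic-migraine cohorts with known ground truth.

The real patient-level data behind the analysis are not publicly available, so
the pipeline is driven by a simulator that reproduces the statistical
structure the analysis assumes:

* a mixed binary/continuous phenotype matrix (comorbidities, headache
  features) tied together by one latent severity factor, so that severity
  strata (headache days/month, exacerbation intensity) are non-empty;
* *confounded* treatment allocation — which preventative classes a patient has
  trialled depends on their features through a softmax propensity model;
* per-class Bernoulli response with a logistic probability model whose
  patient-by-treatment interaction term is scaled by a single
  ``heterogeneity`` knob (``heterogeneity = 0`` switches individual response
  variation off entirely);
* completely-at-random missingness capped at 10% per patient, mirroring the
  exclusion rule of the source cohort.

Everything is deterministic given the config seed, and the generator returns
the :class:`GroundTruth` coefficients so that recovery of individualized
treatment effects can be tested against a known oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .catalog import DEFAULT_CLASSES

__all__ = [
    "SyntheticConfig",
    "CohortTable",
    "GroundTruth",
    "generate_cohort",
    "true_pairwise_effect",
    "inject_missingness",
    "DEFAULT_BASELINE_RESPONSE",
    "DEFAULT_TRIALS_PMF",
]

logger = logging.getLogger(__name__)

#: Default per-class marginal response targets, matching the published overall
#: response rates of the ten classes.
DEFAULT_BASELINE_RESPONSE: dict[str, float] = {
    "botulinum_toxin": 0.47,
    "flunarizine": 0.64,
    "candesartan": 0.16,
    "tca": 0.31,
    "valproate": 0.26,
    "topiramate": 0.29,
    "snri": 0.29,
    "acupuncture": 0.28,
    "betablockers": 0.14,
    "serotonergic": 0.16,
}

#: pmf over the number of distinct classes trialled per patient (1..10).
#: Chosen so the implied quartiles are 2 / 4 / 6 — median 4, IQR 2-6,
#: matching the reported trialling distribution.
DEFAULT_TRIALS_PMF: dict[int, float] = {
    1: 0.08, 2: 0.18, 3: 0.14, 4: 0.14, 5: 0.13,
    6: 0.12, 7: 0.08, 8: 0.06, 9: 0.04, 10: 0.03,
}

# Coefficient scales for the ground-truth logistic response model.  With
# roughly unit-variance continuous features these put ~0.8 sd of shared
# prognostic signal and ~1.0 sd of class-specific interaction signal on the
# logit scale at heterogeneity = 1.
_BETA_SCALE = 0.8
_GAMMA_SCALE = 1.0

MISSINGNESS_CAP = 0.10  # patients above this per-patient missing fraction are dropped


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``heterogeneity`` scales the patient-by-class interaction on the logit
    scale; 0 removes all individual variation in response probabilities.
    ``confounding`` scales how strongly allocation propensities load on the
    features; 0 yields uniformly random allocation.
    """

    n_patients: int = 1446
    n_features: int = 40
    frac_binary: float = 0.5
    classes: tuple[str, ...] = DEFAULT_CLASSES
    heterogeneity: float = 1.0
    confounding: float = 1.0
    baseline_response: Mapping[str, float] | float | None = None
    trials_per_patient: Mapping[int, float] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_features < 2:
            raise ValueError("n_features must be at least 2")
        if not 0.0 <= self.frac_binary <= 1.0:
            raise ValueError("frac_binary must lie in [0, 1]")
        if self.heterogeneity < 0 or self.confounding < 0:
            raise ValueError("heterogeneity and confounding must be non-negative")
        if not 0.0 <= self.missing_rate <= MISSINGNESS_CAP:
            raise ValueError(f"missing_rate must lie in [0, {MISSINGNESS_CAP}]")
        if len(self.classes) < 2:
            raise ValueError("need at least two treatment classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        for p in self.baselines().values():
            if not 0.0 < p < 1.0:
                raise ValueError("baseline_response probabilities must lie in (0, 1)")
        pmf = self.trials_pmf()
        if any(k < 1 or k > len(self.classes) for k in pmf):
            raise ValueError("trials_per_patient support exceeds class count")
        if abs(sum(pmf.values()) - 1.0) > 1e-9:
            raise ValueError("trials_per_patient pmf must sum to 1")

    def baselines(self) -> dict[str, float]:
        """Per-class marginal response targets, resolved from the config."""
        base = self.baseline_response
        if base is None:
            out = {}
            for c in self.classes:
                if c not in DEFAULT_BASELINE_RESPONSE:
                    raise KeyError(
                        f"no default baseline response for class {c!r}; "
                        "supply baseline_response explicitly"
                    )
                out[c] = DEFAULT_BASELINE_RESPONSE[c]
            return out
        if isinstance(base, (int, float)):
            return {c: float(base) for c in self.classes}
        missing = set(self.classes) - set(base)
        if missing:
            raise KeyError(f"baseline_response missing classes: {sorted(missing)}")
        return {c: float(base[c]) for c in self.classes}

    def trials_pmf(self) -> dict[int, float]:
        """pmf over trialled-class counts, truncated to the class count."""
        if self.trials_per_patient is not None:
            pmf = {int(k): float(v) for k, v in self.trials_per_patient.items()}
            total = sum(pmf.values())
            return {k: v / total for k, v in pmf.items()}
        n = len(self.classes)
        pmf = {k: v for k, v in DEFAULT_TRIALS_PMF.items() if k <= n}
        total = sum(pmf.values())
        return {k: v / total for k, v in pmf.items()}


@dataclass
class CohortTable:
    """Patients-by-features table plus per-patient treatment trial records.

    ``patients`` is indexed by ``patient_id`` and holds the feature columns
    together with the two severity fields (``headache_days``,
    ``exacerbation_intensity``).  ``trials`` is a long table with one row per
    (patient, trialled class): ``patient_id, class_name, response,
    order_index``.
    """

    patients: pd.DataFrame
    trials: pd.DataFrame
    feature_columns: list[str]
    binary_columns: list[str]

    def __post_init__(self) -> None:
        missing_cols = set(self.feature_columns) - set(self.patients.columns)
        if missing_cols:
            raise ValueError(f"feature columns absent from table: {sorted(missing_cols)}")
        for col in ("headache_days", "exacerbation_intensity"):
            if col not in self.patients.columns:
                raise ValueError(f"severity field {col!r} missing")
        days = self.patients["headache_days"]
        if ((days < 0) | (days > 31)).any():
            raise ValueError("headache_days must lie in [0, 31]")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.patients.index.to_numpy()

    def feature_matrix(self, patient_ids: Sequence | None = None) -> np.ndarray:
        table = self.patients if patient_ids is None else self.patients.loc[patient_ids]
        return table[self.feature_columns].to_numpy(dtype=float)

    def trialled(self, class_name: str) -> np.ndarray:
        """IDs of patients who trialled ``class_name``."""
        mask = self.trials["class_name"] == class_name
        return self.trials.loc[mask, "patient_id"].unique()

    def responses(self, class_name: str) -> pd.Series:
        """Observed binary response to ``class_name``, indexed by patient_id."""
        rows = self.trials[self.trials["class_name"] == class_name]
        return rows.set_index("patient_id")["response"]

    def subset(self, patient_ids: Sequence) -> "CohortTable":
        ids = pd.Index(patient_ids)
        return CohortTable(
            patients=self.patients.loc[ids].copy(),
            trials=self.trials[self.trials["patient_id"].isin(ids)].reset_index(drop=True),
            feature_columns=list(self.feature_columns),
            binary_columns=list(self.binary_columns),
        )

    def with_features(self, features: pd.DataFrame) -> "CohortTable":
        """Return a copy whose feature columns are replaced by ``features``."""
        patients = self.patients.copy()
        patients[features.columns] = features
        return CohortTable(patients, self.trials.copy(),
                           list(features.columns), list(self.binary_columns))

    # -- IO ------------------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(directory / "patients.csv", index_label="patient_id")
        self.trials.to_csv(directory / "trials.csv", index=False)
        meta = {"feature_columns": self.feature_columns,
                "binary_columns": self.binary_columns}
        (directory / "cohort_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CohortTable":
        directory = Path(directory)
        patients = pd.read_csv(directory / "patients.csv", index_col="patient_id")
        trials = pd.read_csv(directory / "trials.csv")
        meta = json.loads((directory / "cohort_meta.json").read_text())
        return cls(patients, trials, meta["feature_columns"], meta["binary_columns"])


@dataclass
class GroundTruth:
    """True coefficients of the synthetic response and allocation models.

    Response model for class ``c`` at feature vector ``x``::

        p_c(x) = sigmoid(alpha_c + heterogeneity * (beta + gamma_c) . x)

    ``beta`` is a shared prognostic vector, ``gamma_c`` a class-specific
    interaction vector; both are switched off together by ``heterogeneity``
    so that at 0 every patient has the identical per-class probability
    ``sigmoid(alpha_c)``.  Allocation propensity logits are
    ``confounding * delta_c . x``.
    """

    alpha: dict[str, float]
    beta: np.ndarray
    gamma: dict[str, np.ndarray]
    propensity: dict[str, np.ndarray]
    heterogeneity: float
    confounding: float
    feature_columns: list[str]

    def linear_predictor(self, class_name: str, X: np.ndarray) -> np.ndarray:
        if class_name not in self.alpha:
            raise KeyError(f"unknown treatment class {class_name!r}")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        slope = self.heterogeneity * (self.beta + self.gamma[class_name])
        return self.alpha[class_name] + X @ slope

    def response_probability(self, class_name: str, X: np.ndarray) -> np.ndarray:
        """True response probability for every row of ``X``."""
        return expit(self.linear_predictor(class_name, X))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "beta": self.beta.tolist(),
            "gamma": {c: g.tolist() for c, g in self.gamma.items()},
            "propensity": {c: d.tolist() for c, d in self.propensity.items()},
            "heterogeneity": self.heterogeneity,
            "confounding": self.confounding,
            "feature_columns": self.feature_columns,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            alpha={c: float(v) for c, v in d["alpha"].items()},
            beta=np.asarray(d["beta"], dtype=float),
            gamma={c: np.asarray(g, dtype=float) for c, g in d["gamma"].items()},
            propensity={c: np.asarray(g, dtype=float) for c, g in d["propensity"].items()},
            heterogeneity=float(d["heterogeneity"]),
            confounding=float(d["confounding"]),
            feature_columns=list(d["feature_columns"]),
        )


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept a such that mean(sigmoid(a + eta)) == target over the cohort."""
    lo, hi = -30.0, 30.0
    f = lambda a: float(np.mean(expit(a + eta))) - target
    return brentq(f, lo, hi, xtol=1e-10)


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort and its generating coefficients.

    Deterministic given ``config.seed``.  Allocation is confounded: each
    patient trials ``k`` distinct classes (k from the trialling pmf) chosen by
    Gumbel-top-k sampling over softmax propensity logits that depend on the
    features; responses are Bernoulli draws from the ground-truth logistic
    probabilities.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, d = config.n_patients, config.n_features
    classes = list(config.classes)

    n_binary = int(round(config.frac_binary * d))
    n_cont = d - n_binary
    cont_cols = [f"x{j:02d}" for j in range(n_cont)]
    bin_cols = [f"b{j:02d}" for j in range(n_binary)]
    feature_columns = cont_cols + bin_cols

    # One latent severity factor ties features and severity fields together.
    severity = rng.standard_normal(n)

    X_cont = np.empty((n, n_cont))
    for j in range(n_cont):
        lam = rng.uniform(0.0, 0.5)
        X_cont[:, j] = lam * severity + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)

    X_bin = np.empty((n, n_binary))
    for j in range(n_binary):
        prevalence = rng.uniform(0.2, 0.8)
        slope = rng.uniform(0.0, 0.8)
        p = expit(logit(prevalence) + slope * severity)
        X_bin[:, j] = rng.random(n) < p

    X = np.hstack([X_cont, X_bin])

    headache_days = np.clip(
        np.round(25.4 + 5.0 * severity + rng.normal(0.0, 5.7, size=n)), 0, 31
    ).astype(int)
    intensity = np.clip(
        np.round(8.2 + 0.8 * severity + rng.normal(0.0, 1.0, size=n)), 0, 10
    ).astype(int)

    # Ground-truth coefficients.
    beta = rng.normal(0.0, _BETA_SCALE / np.sqrt(d), size=d)
    gamma = {c: rng.normal(0.0, _GAMMA_SCALE / np.sqrt(d), size=d) for c in classes}
    delta = {c: rng.normal(0.0, 1.0 / np.sqrt(d), size=d) for c in classes}
    alpha = {}
    for c, target in config.baselines().items():
        eta = config.heterogeneity * (X @ (beta + gamma[c]))
        alpha[c] = _calibrate_intercept(eta, target)

    gt = GroundTruth(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        propensity=delta,
        heterogeneity=config.heterogeneity,
        confounding=config.confounding,
        feature_columns=feature_columns,
    )

    # Confounded allocation: Gumbel-top-k over propensity logits.
    pmf = config.trials_pmf()
    ks = rng.choice(list(pmf), size=n, p=list(pmf.values()))
    logits = config.confounding * np.column_stack([X @ delta[c] for c in classes])
    gumbel = rng.gumbel(size=(n, len(classes)))
    scores = logits + gumbel

    probs = {c: gt.response_probability(c, X) for c in classes}
    draws = rng.random((n, len(classes)))

    records = []
    for i in range(n):
        chosen = np.argsort(-scores[i])[: ks[i]]
        for order, ci in enumerate(chosen):
            c = classes[ci]
            records.append(
                (i, c, int(draws[i, ci] < probs[c][i]), order)
            )
    trials = pd.DataFrame(records,
                          columns=["patient_id", "class_name", "response", "order_index"])

    patients = pd.DataFrame(X, columns=feature_columns)
    patients.index.name = "patient_id"
    patients["headache_days"] = headache_days
    patients["exacerbation_intensity"] = intensity

    cohort = CohortTable(patients, trials, feature_columns, bin_cols)
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate,
                                    seed=int(rng.integers(2**31)))
    return cohort, gt


def true_pairwise_effect(
    gt: GroundTruth, features: np.ndarray, class_a: str, class_b: str
) -> np.ndarray:
    """Ground-truth pairwise effect ``p_A(x) - p_B(x)`` for each row of ``features``.

    Returns a scalar for a single feature vector.
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    out = gt.response_probability(class_a, X) - gt.response_probability(class_b, X)
    return float(out[0]) if single else out


def inject_missingness(
    cohort: CohortTable, missing_rate: float, seed: int = 0
) -> CohortTable:
    """Mask feature cells completely at random; drop patients over the 10% cap.

    Patients whose masked-feature fraction exceeds 10% are removed from the
    cohort (both tables), mirroring the exclusion rule applied to the source
    data; the drop count is logged.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    if missing_rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    features = cohort.patients[cohort.feature_columns].copy()
    mask = rng.random(features.shape) < missing_rate
    values = features.to_numpy(dtype=float)
    values[mask] = np.nan
    features.iloc[:, :] = values

    frac_missing = mask.mean(axis=1)
    keep = frac_missing <= MISSINGNESS_CAP
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("inject_missingness: dropped %d patients over the %.0f%% cap",
                    n_dropped, 100 * MISSINGNESS_CAP)

    patients = cohort.patients.copy()
    patients[cohort.feature_columns] = features
    patients = patients.loc[keep]
    trials = cohort.trials[cohort.trials["patient_id"].isin(patients.index)]
    return CohortTable(patients, trials.reset_index(drop=True),
                       list(cohort.feature_columns), list(cohort.binary_columns))
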