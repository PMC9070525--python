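"""Machine-prescription impact model: sequences, time-to-response, costs.

Given per-patient response probabilities p_1..p_n for a sequence of
preventative classes trialled one after another, the chance that the first
success arrives at trial k+1 (after k failures) is

    P{X=k} = (1 - p_1) ... (1 - p_k) p_{k+1},

with residual failure mass prod_i (1 - p_i).  The expected months in pain
before a successful trial completes is sum_k P{X=k} T_k, where T_k is the
cumulative evaluation time through trial k+1; with a homogeneous per-trial
duration t this is the familiar (k+1) t P{X=k} sum.  Because evaluation
durations are not homogeneous here (6 months for onabotulinumtoxinA, 3
otherwise) the general cumulative-duration form is used, and both the
unconditional expectation and the expectation conditional on eventual success
(normalized by 1 - residual) are available; the conditional variant is the
headline quantity, since the residual mass otherwise deflates the times of
poor responders.

Machine prescription orders each patient's classes by descending modelled
ITE; comparator policies (guideline sequences, an expert order, random, and
cost-ordered) are built per the published constructions, with all randomized
policies evaluated by seeded Monte Carlo over sequence realizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import BOTULINUM_TOXIN, TreatmentCatalog
from .effects import TestResult
from .synthetic import CohortTable

__all__ = [
    "SuccessPmf",
    "ite_to_probability",
    "rank_by_ite",
    "success_pmf",
    "expected_time_to_response",
    "build_comparator_sequence",
    "evaluate_policy",
    "compare_policies",
    "topk_coverage",
    "policy_cost",
    "cost_delta",
    "sensitivity_strata",
    "POLICY_LABELS",
]

POLICY_LABELS = (
    "machine", "machine_restricted", "guideline1", "guideline2",
    "nice", "expert", "random", "cost_ordered",
)

_RANDOMIZED = {"guideline1", "guideline2", "nice", "random"}

#: Pools used by the guideline constructions.
GUIDELINE1_POOL = ("tca", "snri", "betablockers", "candesartan",
                   "topiramate", "valproate", "flunarizine")
GUIDELINE2_FIRST_POOL = ("betablockers", "candesartan", "tca", "snri")
GUIDELINE2_SECOND_POOL = ("topiramate", "valproate", "flunarizine")
NICE_POOL = ("betablockers", "topiramate", "tca")

#: Default expert-panel order: a synthetic placeholder (the surveyed expert
#: aggregate is not public), set to the published modelled-effect rank.
DEFAULT_EXPERT_ORDER = (
    BOTULINUM_TOXIN, "flunarizine", "candesartan", "tca", "valproate",
    "topiramate", "snri", "acupuncture", "betablockers", "serotonergic",
)


# ---------------------------------------------------------------------------
# Probabilities and sequences
# ---------------------------------------------------------------------------

def ite_to_probability(ite, floor: float = 0.01, ceiling: float = 0.99):
    """Read an ITE as a response probability, clamped to [floor, ceiling].

    Pairwise-mean ITEs can stray outside [0, 1]; the success pmf needs proper
    probabilities, so values are clamped.  Works elementwise on arrays.
    """
    arr = np.asarray(ite, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("ITE values must be finite")
    out = np.clip(arr, floor, ceiling)
    return float(out) if np.isscalar(ite) or arr.ndim == 0 else out


def rank_by_ite(
    ites: Mapping[str, float],
    restricted: bool = False,
    restricted_class: str = BOTULINUM_TOXIN,
    restricted_position: int = 4,
) -> list[str]:
    """Order classes by descending ITE; ties broken alphabetically.

    ``restricted`` forces ``restricted_class`` to the given 1-based position
    (fourth by default), with the remaining classes in descending order
    around it.
    """
    for c, v in ites.items():
        if v is None or not np.isfinite(v):
            raise ValueError(f"ITE missing or non-finite for class {c!r}")
    order = sorted(ites, key=lambda c: (-ites[c], c))
    if not restricted:
        return order
    if restricted_class not in ites:
        raise KeyError(f"{restricted_class!r} not among the supplied classes")
    rest = [c for c in order if c != restricted_class]
    pos = min(restricted_position - 1, len(rest))
    return rest[:pos] + [restricted_class] + rest[pos:]


@dataclass(frozen=True)
class SuccessPmf:
    """P{X=k} for k failures before the first success, plus residual mass."""

    probs: np.ndarray   # per-trial success probabilities, in order
    pmf: np.ndarray     # P{X=k}, k = 0..n-1
    residual: float     # probability that no trial succeeds

    def __post_init__(self) -> None:
        total = self.pmf.sum() + self.residual
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pmf and residual sum to {total}, not 1")


def success_pmf(p: Sequence[float]) -> SuccessPmf:
    """First-success pmf over a sequence of independent trials."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    fail_before = np.concatenate([[1.0], np.cumprod(1.0 - p)[:-1]])
    pmf = fail_before * p
    residual = float(np.prod(1.0 - p))
    return SuccessPmf(probs=p, pmf=pmf, residual=residual)


def expected_time_to_response(
    sequence: Sequence[str],
    p: Sequence[float],
    catalog: TreatmentCatalog,
    conditional: bool = True,
) -> float:
    """Expected months to completion of the first successful trial.

    ``T_k`` is the cumulative evaluation duration through trial k+1, taken
    from the catalog per class; with homogeneous durations this reduces to
    the (k+1) t P{X=k} form.  ``conditional=True`` (default) normalizes by
    the probability of eventual success.
    """
    sequence = list(sequence)
    if not sequence:
        raise ValueError("sequence is empty")
    p = np.asarray(p, dtype=float)
    if len(p) != len(sequence):
        raise ValueError("p must align with the sequence")
    pmf = success_pmf(p)
    T = np.cumsum(catalog.durations(sequence))
    unconditional = float(np.sum(pmf.pmf * T))
    if not conditional:
        return unconditional
    success_mass = 1.0 - pmf.residual
    if success_mass <= 0:
        raise ValueError("conditional expectation undefined: success probability is 0")
    return unconditional / success_mass


# ---------------------------------------------------------------------------
# Comparator policies
# ---------------------------------------------------------------------------

def build_comparator_sequence(
    label: str,
    catalog: TreatmentCatalog,
    seed: int = 0,
    n_realizations: int = 1000,
    expert_order: Sequence[str] | None = None,
    tariff_level: str = "low",
) -> list[list[str]]:
    """Realization set of treatment sequences for a comparator policy.

    Deterministic policies (expert, cost_ordered) return a single realization;
    randomized ones (guideline1, guideline2, nice, random) return
    ``n_realizations`` seeded draws.  Guideline sequences end at
    onabotulinumtoxinA (fourth) as published; the random policy permutes the
    whole catalog.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    names = catalog.names

    def _require(pool):
        missing = [c for c in pool if c not in catalog]
        if missing:
            raise ValueError(f"policy {label!r} needs classes {missing} in the catalog")

    if label == "expert":
        order = list(expert_order) if expert_order is not None else [
            c for c in DEFAULT_EXPERT_ORDER if c in catalog]
        unknown = [c for c in order if c not in catalog]
        if unknown:
            raise ValueError(f"expert order contains unknown classes {unknown}")
        return [order]
    if label == "cost_ordered":
        return [sorted(names, key=lambda c: (catalog.tariff(c, tariff_level), c))]
    if label == "random":
        return [list(rng.permutation(names)) for _ in range(n_realizations)]
    if label == "guideline1":
        _require(GUIDELINE1_POOL + (BOTULINUM_TOXIN,))
        pool = [c for c in GUIDELINE1_POOL]
        return [list(rng.choice(pool, size=3, replace=False)) + [BOTULINUM_TOXIN]
                for _ in range(n_realizations)]
    if label == "guideline2":
        _require(GUIDELINE2_FIRST_POOL + GUIDELINE2_SECOND_POOL + (BOTULINUM_TOXIN,))
        out = []
        for _ in range(n_realizations):
            first = list(rng.choice(GUIDELINE2_FIRST_POOL, size=2, replace=False))
            second = [str(rng.choice(GUIDELINE2_SECOND_POOL))]
            out.append(first + second + [BOTULINUM_TOXIN])
        return out
    if label == "nice":
        _require(NICE_POOL + (BOTULINUM_TOXIN,))
        return [list(rng.permutation(NICE_POOL)) + [BOTULINUM_TOXIN]
                for _ in range(n_realizations)]
    raise ValueError(f"unknown policy label {label!r}")


# ---------------------------------------------------------------------------
# Policy evaluation
# ---------------------------------------------------------------------------

def _months_for_sequences(
    prob_table: pd.DataFrame,
    sequences: Sequence[Sequence[str]],
    catalog: TreatmentCatalog,
    conditional: bool,
) -> np.ndarray:
    """Per-patient expected months averaged over sequence realizations.

    ``sequences`` is either one sequence per realization (applied to all
    patients) or one sequence per patient per realization (2-D list).
    """
    n = len(prob_table)
    acc = np.zeros(n)
    for seq in sequences:
        P = prob_table[list(seq)].to_numpy()
        T = np.cumsum(catalog.durations(seq))
        fail_before = np.hstack([np.ones((n, 1)), np.cumprod(1.0 - P, axis=1)[:, :-1]])
        pmf = fail_before * P
        months = pmf @ T
        if conditional:
            success_mass = 1.0 - np.prod(1.0 - P, axis=1)
            if (success_mass <= 0).any():
                raise ValueError("conditional expectation undefined for some patient")
            months = months / success_mass
        acc += months
    return acc / len(sequences)


def evaluate_policy(
    ites: pd.DataFrame,
    policy: str,
    catalog: TreatmentCatalog,
    n_realizations: int = 1000,
    seed: int = 0,
    conditional: bool = True,
    expert_order: Sequence[str] | None = None,
    tariff_level: str = "low",
    eval_probs: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-patient expected months-to-response under a prescription policy.

    ``ites`` (patients x classes) drives both the machine ranking and —
    unless ``eval_probs`` supplies external (e.g. ground-truth) response
    probabilities — the success probabilities, via the clamped ITE-to-
    probability map.  Randomized comparator policies are averaged over
    ``n_realizations`` seeded draws per patient.
    """
    classes = [c for c in catalog.names if c in ites.columns]
    if len(classes) != len(catalog.names):
        missing = set(catalog.names) - set(ites.columns)
        raise ValueError(f"ITEs missing for classes {sorted(missing)}")
    if ites[classes].isna().any().any():
        raise ValueError("ITEs must be defined for every patient and class")
    prob = (pd.DataFrame(ite_to_probability(ites[classes].to_numpy()),
                         index=ites.index, columns=classes)
            if eval_probs is None else eval_probs[classes].astype(float))
    if eval_probs is not None and (((prob < 0) | (prob > 1)).any().any()):
        raise ValueError("eval_probs must lie in [0, 1]")

    n = len(prob)
    if policy in ("machine", "machine_restricted"):
        months = np.empty(n)
        restricted = policy == "machine_restricted"
        for i, (pid, row) in enumerate(ites[classes].iterrows()):
            seq = rank_by_ite(row.to_dict(), restricted=restricted)
            months[i] = expected_time_to_response(
                seq, prob.loc[pid, seq].to_numpy(), catalog, conditional=conditional)
        return pd.Series(months, index=prob.index, name=policy)

    sequences = build_comparator_sequence(
        policy, catalog, seed=seed, n_realizations=n_realizations,
        expert_order=expert_order, tariff_level=tariff_level,
    )
    months = _months_for_sequences(prob, sequences, catalog, conditional)
    return pd.Series(months, index=prob.index, name=policy)


def compare_policies(months_a: Sequence[float], months_b: Sequence[float]) -> TestResult:
    """Two-tailed Welch t-test between two policy time-to-response vectors.

    Reports mean(a) - mean(b) with a 95% CI on the Welch degrees of freedom
    (negative = policy a faster).
    """
    a = np.asarray(months_a, dtype=float)
    b = np.asarray(months_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("policy distributions cover different patients")
    res = stats.ttest_ind(a, b, equal_var=False)
    diff = a.mean() - b.mean()
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    df = float(res.df)
    crit = stats.t.ppf(0.975, df)
    return TestResult(mean_difference=float(diff),
                      ci_lower=float(diff - crit * se),
                      ci_upper=float(diff + crit * se),
                      p_value=float(res.pvalue), df=df,
                      statistic=float(res.statistic))


# ---------------------------------------------------------------------------
# Coverage, costs, strata
# ---------------------------------------------------------------------------

def topk_coverage(ites: pd.DataFrame, trials: pd.DataFrame, k: int) -> float:
    """Fraction of patients whose trialled classes reach their top-k ranking.

    Patients with no trial history never count as covered.  ``trials`` is a
    long table with ``patient_id`` and ``class_name`` columns.
    """
    if not 1 <= k <= ites.shape[1]:
        raise ValueError("k must lie within the catalog size")
    tried = trials.groupby("patient_id")["class_name"].agg(set)
    covered = 0
    for pid, row in ites.iterrows():
        top = rank_by_ite(row.dropna().to_dict())[:k]
        if pid in tried.index and tried.loc[pid] & set(top):
            covered += 1
    return covered / len(ites)


def policy_cost(
    sequence: Sequence[str],
    n_trials: int,
    catalog: TreatmentCatalog,
    tariff_level: str = "low",
) -> float:
    """Cumulative tariff (pounds) of the first ``n_trials`` of a sequence."""
    if n_trials > len(sequence):
        raise ValueError("n_trials exceeds the sequence length")
    return float(sum(catalog.tariff(c, tariff_level) for c in list(sequence)[:n_trials]))


def cost_delta(
    predicted_sequence: Sequence[str],
    actual_sequence: Sequence[str],
    n_trials: int,
    catalog: TreatmentCatalog,
    tariff_level: str = "low",
) -> float:
    """Predicted-minus-actual cost over the first ``n_trials`` trials.

    Negative values mean machine prescription is cheaper than what was
    actually trialled.
    """
    return (policy_cost(predicted_sequence, n_trials, catalog, tariff_level)
            - policy_cost(actual_sequence, n_trials, catalog, tariff_level))


def sensitivity_strata(cohort: CohortTable) -> tuple[pd.Series, pd.Series]:
    """Severity strata masks: (severe, less_severe), indexed by patient.

    Severe: >= 25 headache days/month AND exacerbation intensity >= 9.
    Less severe: < 25 days AND intensity < 9.  Patients matching neither
    conjunction belong to no stratum.
    """
    for col in ("headache_days", "exacerbation_intensity"):
        if col not in cohort.patients.columns:
            raise ValueError(f"severity field {col!r} missing")
    days = cohort.patients["headache_days"]
    intensity = cohort.patients["exacerbation_intensity"]
    severe = (days >= 25) & (intensity >= 9)
    less_severe = (days < 25) & (intensity < 9)
    return severe, less_severe
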