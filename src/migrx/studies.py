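"""Bundled simulation studies on synthetic cohorts with known ground truth.

These are the package's standing validation experiments; the test suite and
the reproduction script both run them.  Problem sizes are deliberately
moderate (hundreds of patients, a handful of classes) so a study completes in
minutes on one core while leaving enough signal for the qualitative claims:

* ``pair_recovery_study`` — how well the pairwise multitask GP recovers the
  ground-truth effect surface (Pearson correlation and PEHE, the RMSE between
  estimated and true pairwise effects), and that PEHE shrinks with more
  training data;
* ``heterogeneity_study`` — the central contrast: conditional (above-median
  modelled ITE) true response rates exceed overall true response rates when
  patient-by-treatment interactions exist, and the contrast vanishes when
  they are switched off;
* ``policy_benefit_study`` — machine prescription reaches a successful trial
  sooner than a random trialling order when responsiveness is heterogeneous,
  with time-to-response scored under the *ground-truth* response
  probabilities so the comparison is not circular;
* ``homogeneous_policy_check`` — with identical response probabilities
  everywhere, ordering cannot matter and machine and random policies
  coincide exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import TreatmentCatalog
from .cmgp import assemble_pair_dataset, fit_cmgp, predict_pair_ite
from .effects import TestResult, aggregate_class_ite, summarize_effects
from .gp import KernelConfig
from .policy import compare_policies, evaluate_policy
from .preprocess import SplitSpec, apply_imputer, fit_imputer, stratified_split
from .synthetic import (CohortTable, SyntheticConfig, generate_cohort,
                        true_pairwise_effect)

__all__ = [
    "RECOVERY_CLASSES", "HETEROGENEITY_CLASSES",
    "pair_recovery_study", "heterogeneity_study", "HeterogeneityRun",
    "pooled_heterogeneity_contrast", "policy_benefit_study",
    "homogeneous_policy_check",
]

#: Two-class study: every patient trials exactly one of the pair, allocated
#: by the confounded propensity model.
RECOVERY_CLASSES = ("tca", "topiramate")

#: Four classes with spread baseline response rates for the end-to-end
#: heterogeneity and policy studies (six pair models per run).
HETEROGENEITY_CLASSES = ("tca", "topiramate", "betablockers", "flunarizine")

#: Single fast kernel family for the large property studies.
_STUDY_KERNEL = KernelConfig(kernel="rbf", ard=False, n_restarts=1, max_iter=50)


# ---------------------------------------------------------------------------
# Pairwise recovery
# ---------------------------------------------------------------------------

def pair_recovery_study(
    seeds: tuple[int, ...] = (0, 1, 2),
    n_rows: int = 800,
    sizes: tuple[int, ...] = (100, 300, 800),
    heterogeneity: float = 1.0,
) -> dict:
    """Recovery of the true pairwise effect by the multitask GP.

    For each seed a confounded two-class cohort of ``n_rows`` patients (one
    trial each) is drawn; models trained on nested subsets of the pair data
    are scored on the full cohort against the ground-truth effect.  Returns
    per-seed Pearson correlations at the largest size and the PEHE curve
    over ``sizes``.
    """
    a, b = RECOVERY_CLASSES
    rs, pehe_curves = [], []
    for seed in seeds:
        cfg = SyntheticConfig(n_patients=n_rows, classes=RECOVERY_CLASSES,
                              trials_per_patient={1: 1.0},
                              heterogeneity=heterogeneity, seed=seed)
        cohort, gt = generate_cohort(cfg)
        imputer = fit_imputer(cohort, n_components=10, seed=seed)
        scaled = apply_imputer(imputer, cohort)
        pair = assemble_pair_dataset(scaled, a, b)
        tau_true = true_pairwise_effect(gt, cohort.feature_matrix(), a, b)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
        pehes = []
        for n in sizes:
            idx = np.sort(rng.choice(pair.n_rows, size=min(n, pair.n_rows),
                                     replace=False))
            model = fit_cmgp(pair.subset(idx), _STUDY_KERNEL, seed=seed)
            tau_hat = predict_pair_ite(model, scaled).tau
            pehes.append(float(np.sqrt(np.mean((tau_hat - tau_true) ** 2))))
            if n == max(sizes):
                rs.append(float(stats.pearsonr(tau_hat, tau_true)[0]))
        pehe_curves.append(pehes)
    pehe_curves = np.asarray(pehe_curves)
    return {
        "seeds": list(seeds),
        "sizes": list(sizes),
        "pearson_r": rs,
        "median_r": float(np.median(rs)),
        "pehe_per_seed": pehe_curves,
        "pehe_median": np.median(pehe_curves, axis=0).tolist(),
    }


# ---------------------------------------------------------------------------
# Heterogeneity detection
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityRun:
    """One end-to-end run of the ITE analysis on a synthetic cohort."""

    heterogeneity: float
    seed: int
    cohort: CohortTable
    ground_truth: object
    test_cohort: CohortTable
    ites: pd.DataFrame
    effect_summary: pd.DataFrame
    diffs: np.ndarray  # per-class conditional_true - overall_true


def heterogeneity_study(
    heterogeneity: float,
    seed: int,
    n_patients: int = 1000,
    classes: tuple[str, ...] = HETEROGENEITY_CLASSES,
) -> HeterogeneityRun:
    """Full split/impute/fit/aggregate run; returns the per-class contrast.

    The model never sees the test partition; ITEs, the above-median
    conditional subgroup and the true response rates are all computed
    out-of-sample.
    """
    cfg = SyntheticConfig(n_patients=n_patients, classes=classes,
                          heterogeneity=heterogeneity, seed=seed)
    cohort, gt = generate_cohort(cfg)
    train, val, test = stratified_split(cohort, SplitSpec(seed=seed))
    imputer = fit_imputer(train, n_components=10, seed=seed)
    train_i, val_i, test_i = (apply_imputer(imputer, p)
                              for p in (train, val, test))
    trainval = CohortTable(
        pd.concat([train_i.patients, val_i.patients]).sort_index(),
        pd.concat([train_i.trials, val_i.trials], ignore_index=True),
        train_i.feature_columns, train_i.binary_columns)
    pairwise = {}
    for a, b in itertools.combinations(classes, 2):
        pair = assemble_pair_dataset(trainval, a, b)
        model = fit_cmgp(pair, _STUDY_KERNEL, seed=seed)
        pairwise[(a, b)] = predict_pair_ite(model, test_i).as_series()
    ites = aggregate_class_ite(pairwise, classes=list(classes))
    summary = summarize_effects(ites, test_i, classes=list(classes))
    diffs = (summary["conditional_true"] - summary["overall_true"]).to_numpy()
    return HeterogeneityRun(heterogeneity=heterogeneity, seed=seed,
                            cohort=cohort, ground_truth=gt,
                            test_cohort=test_i, ites=ites,
                            effect_summary=summary, diffs=diffs)


def pooled_heterogeneity_contrast(runs: list[HeterogeneityRun]) -> dict:
    """Pool per-class contrasts across runs; one-sample t against zero."""
    diffs = np.concatenate([r.diffs for r in runs])
    diffs = diffs[~np.isnan(diffs)]
    mean = float(diffs.mean())
    se = float(diffs.std(ddof=1) / np.sqrt(len(diffs)))
    t, p = stats.ttest_1samp(diffs, 0.0)
    return {"mean": mean, "se": se, "t": float(t), "p": float(p),
            "n": int(len(diffs))}


# ---------------------------------------------------------------------------
# Policy benefit
# ---------------------------------------------------------------------------

def _true_prob_table(run: HeterogeneityRun, classes) -> pd.DataFrame:
    Xraw = run.cohort.feature_matrix(run.ites.index)
    return pd.DataFrame(
        {c: run.ground_truth.response_probability(c, Xraw) for c in classes},
        index=run.ites.index)


def policy_benefit_study(
    run: HeterogeneityRun,
    n_realizations: int = 1000,
    seed: int = 0,
) -> dict:
    """Machine vs random trialling order, scored under ground-truth response
    probabilities (the modelled ITEs decide only the ordering)."""
    classes = list(run.ites.columns)
    catalog = TreatmentCatalog.default(classes)
    true_p = _true_prob_table(run, classes)
    machine = evaluate_policy(run.ites, "machine", catalog,
                              eval_probs=true_p, seed=seed)
    random_policy = evaluate_policy(run.ites, "random", catalog,
                                    n_realizations=n_realizations,
                                    eval_probs=true_p, seed=seed)
    res = compare_policies(machine, random_policy)
    return {"machine_mean": float(machine.mean()),
            "random_mean": float(random_policy.mean()),
            "test": res}


def homogeneous_policy_check(seed: int = 0, n_patients: int = 200) -> dict:
    """With identical response probabilities everywhere, ordering is moot.

    Ranks patients by arbitrary seeded pseudo-ITEs but scores months under a
    constant ground-truth probability table, so machine and random policies
    must coincide exactly (equal per-trial durations).
    """
    classes = list(HETEROGENEITY_CLASSES)
    catalog = TreatmentCatalog.default(classes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    index = pd.Index(range(n_patients), name="patient_id")
    ites = pd.DataFrame(rng.normal(0.2, 0.1, size=(n_patients, len(classes))),
                        index=index, columns=classes)
    true_p = pd.DataFrame(0.3, index=index, columns=classes)
    machine = evaluate_policy(ites, "machine", catalog, eval_probs=true_p,
                              seed=seed)
    random_policy = evaluate_policy(ites, "random", catalog,
                                    n_realizations=200, eval_probs=true_p,
                                    seed=seed)
    return {"machine": machine, "random": random_policy,
            "max_abs_diff": float(np.max(np.abs(machine - random_policy)))}
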