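"""End-to-end orchestration: simulate -> preprocess -> fit -> effects -> policy.

``run_pipeline`` drives the whole analysis on a synthetic cohort with a
single global seed, fanning out deterministic per-stage seeds, and returns
(and optionally writes) every analysis product: the cohort and partition
tables, per-pair ITEs, the per-class effect summary with the
conditional-vs-overall contrast, per-class CV validation accuracies, policy
time-to-response distributions with pairwise tests, top-k coverage, cost
deltas and the severity-strata sensitivity analysis, plus a JSON run
manifest.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .catalog import BOTULINUM_TOXIN, TreatmentCatalog
from .cmgp import (MIN_ROWS_PER_ARM, assemble_pair_dataset, fit_cmgp,
                   predict_pair_ite, select_kernel)
from .effects import (AnalysisConfig, TestResult, aggregate_class_ite,
                      cv_validation_accuracy, paired_difference_test,
                      reference_rate_vectors, summarize_effects)
from .gp import KernelConfig
from .policy import (compare_policies, cost_delta, evaluate_policy,
                     rank_by_ite, sensitivity_strata, topk_coverage)
from .preprocess import (SplitSpec, apply_imputer, fit_imputer,
                         partition_frame, stratified_split)
from .synthetic import CohortTable, SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_reference_comparison", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "split", "impute", "fit", "effects", "policy")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), 100 + idx])
    return int(ss.generate_state(1)[0] % 2**31)


def default_kernel_candidates() -> list[KernelConfig]:
    """The default selection grid: {RBF, Matern-5/2} x {ARD off, on}."""
    return [
        KernelConfig(kernel="rbf", ard=False),
        KernelConfig(kernel="matern52", ard=False),
        KernelConfig(kernel="rbf", ard=True),
        KernelConfig(kernel="matern52", ard=True),
    ]


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis end to end."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    split: SplitSpec | None = None
    kernel_candidates: list[KernelConfig] = field(
        default_factory=lambda: [KernelConfig(kernel="rbf", ard=False),
                                 KernelConfig(kernel="matern52", ard=False)])
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    catalog: TreatmentCatalog | None = None
    n_components: int = 10
    n_realizations: int = 1000
    min_rows_per_arm: int = MIN_ROWS_PER_ARM
    n_restarts: int | None = None
    conditional_expectation: bool = True
    expert_order: Sequence[str] | None = None
    output_dir: str | Path | None = None
    seed: int = 0

    def resolved_catalog(self) -> TreatmentCatalog:
        if self.catalog is not None:
            return self.catalog
        return TreatmentCatalog.default(self.synthetic.classes)


@dataclass
class PipelineResult:
    """Bundle of every analysis product of one pipeline run."""

    cohort: CohortTable
    partitions: pd.DataFrame
    ites: pd.DataFrame                    # test-partition patients x classes
    pairwise_long: pd.DataFrame           # patient_id, class_a, class_b, tau
    effect_summary: pd.DataFrame
    heterogeneity_test: TestResult | None
    cv_accuracy: pd.DataFrame
    policy_months: pd.DataFrame           # patients x policies
    policy_tests: pd.DataFrame
    topk: dict[int, float]
    cost_summary: pd.DataFrame
    strata_tests: pd.DataFrame
    manifest: dict


def _fit_pair_models(train, val, trainval, test, classes, config, fit_seed):
    """Select kernels on validation DCG, refit on train+val, predict test."""
    pairwise = {}
    pairwise_rows = []
    selected = {}
    for class_a, class_b in itertools.combinations(classes, 2):
        pair_train = assemble_pair_dataset(train, class_a, class_b,
                                           config.min_rows_per_arm)
        kconf = config.kernel_candidates[0]
        if len(config.kernel_candidates) > 1:
            pair_val = assemble_pair_dataset(val, class_a, class_b,
                                             min_rows_per_arm=1)
            kconf = select_kernel(pair_train, pair_val,
                                  config.kernel_candidates, seed=fit_seed)
        pair_full = assemble_pair_dataset(trainval, class_a, class_b,
                                          config.min_rows_per_arm)
        model = fit_cmgp(pair_full, kconf, seed=fit_seed,
                         n_restarts=config.n_restarts)
        selected[f"{class_a}|{class_b}"] = kconf.label
        eff = predict_pair_ite(model, test)
        pairwise[(class_a, class_b)] = eff.as_series()
        pairwise_rows.append(pd.DataFrame({
            "patient_id": eff.patient_ids, "class_a": class_a,
            "class_b": class_b, "tau": eff.tau, "partition": "test",
        }))
    return pairwise, pd.concat(pairwise_rows, ignore_index=True), selected


def _merge_cohorts(parts: Sequence[CohortTable]) -> CohortTable:
    patients = pd.concat([p.patients for p in parts]).sort_index()
    trials = pd.concat([p.trials for p in parts], ignore_index=True)
    return CohortTable(patients, trials, list(parts[0].feature_columns),
                       list(parts[0].binary_columns))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; idempotent given the config seed."""
    catalog = config.resolved_catalog()
    classes = [c for c in catalog.names]

    # 1. simulate ----------------------------------------------------------
    syn = config.synthetic
    if syn.seed == 0 and config.seed != 0:
        from dataclasses import replace
        syn = replace(syn, seed=stage_seed(config.seed, "simulate"))
    cohort, ground_truth = generate_cohort(syn)
    logger.info("simulate: %d patients, %d trials",
                cohort.n_patients, len(cohort.trials))

    # 2. split + impute ----------------------------------------------------
    split = config.split or SplitSpec(seed=stage_seed(config.seed, "split"))
    train, val, test = stratified_split(cohort, split)
    imputer = fit_imputer(train, n_components=min(config.n_components,
                                                  len(cohort.feature_columns) - 1),
                          seed=stage_seed(config.seed, "impute"))
    train_i, val_i, test_i = (apply_imputer(imputer, part)
                              for part in (train, val, test))
    trainval_i = _merge_cohorts([train_i, val_i])

    # 3. pairwise CMGP fits ------------------------------------------------
    fit_seed = stage_seed(config.seed, "fit")
    pairwise, pairwise_long, selected = _fit_pair_models(
        train_i, val_i, trainval_i, test_i, classes, config, fit_seed)

    # 4. effects -----------------------------------------------------------
    ites = aggregate_class_ite(pairwise, classes=classes)
    effect_summary = summarize_effects(ites, test_i, classes=classes)
    defined = effect_summary.dropna(subset=["overall_true", "conditional_true"])
    het_test = None
    if len(defined) >= 2:
        try:
            het_test = paired_difference_test(defined["overall_true"],
                                              defined["conditional_true"])
        except ValueError as exc:
            warnings.warn(f"heterogeneity contrast unavailable: {exc}",
                          UserWarning, stacklevel=2)

    cv_rows = []
    for c in classes:
        resp = test_i.responses(c)
        resp = resp[~resp.index.duplicated(keep="first")]
        resp = resp[resp.index.isin(ites.index)]
        vals = ites.loc[resp.index, c].dropna()
        resp = resp.loc[vals.index]
        if len(resp) >= 10 and resp.nunique() == 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                acc, sd = cv_validation_accuracy(
                    vals.to_numpy(), resp.to_numpy(),
                    folds=min(10, len(resp)),
                    seed=stage_seed(config.seed, "effects"))
            cv_rows.append({"class_name": c, "accuracy": acc, "sd": sd,
                            "n": len(resp)})
        else:
            cv_rows.append({"class_name": c, "accuracy": np.nan, "sd": np.nan,
                            "n": len(resp)})
    cv_accuracy = pd.DataFrame(cv_rows).set_index("class_name")

    # 5. policy ------------------------------------------------------------
    policy_seed = stage_seed(config.seed, "policy")
    policies = ["machine", "random", "expert", "cost_ordered"]
    if BOTULINUM_TOXIN in catalog and len(classes) >= 4:
        policies.insert(1, "machine_restricted")
        for label, pool in (("guideline1", ("tca", "snri", "betablockers",
                                            "candesartan", "topiramate",
                                            "valproate", "flunarizine")),
                            ("guideline2", ("betablockers", "candesartan",
                                            "tca", "snri", "topiramate",
                                            "valproate", "flunarizine")),
                            ("nice", ("betablockers", "topiramate", "tca"))):
            if all(c in catalog for c in pool):
                policies.append(label)

    months = {}
    for label in policies:
        months[label] = evaluate_policy(
            ites, label, catalog, n_realizations=config.n_realizations,
            seed=policy_seed, conditional=config.conditional_expectation,
            expert_order=config.expert_order)
    policy_months = pd.DataFrame(months)

    test_rows = []
    for label in policies:
        if label == "machine":
            continue
        res = compare_policies(policy_months["machine"], policy_months[label])
        test_rows.append({
            "comparison": f"machine_vs_{label}",
            "mean_difference": res.mean_difference,
            "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
            "p_value": res.p_value,
            "significant": res.p_value < config.analysis.alpha_prescriptive,
        })
    policy_tests = pd.DataFrame(test_rows)

    topk = {k: topk_coverage(ites, test_i.trials, k)
            for k in (1, 2, 3) if k <= len(classes)}

    # cost deltas: machine top-n vs the patient's actual first n trials
    deltas_low, deltas_high = [], []
    actual_order = test_i.trials.sort_values("order_index").groupby("patient_id")[
        "class_name"].agg(list)
    for pid, row in ites.iterrows():
        if pid not in actual_order.index:
            continue
        actual = actual_order.loc[pid]
        n_tr = min(len(actual), len(classes))
        predicted = rank_by_ite(row.to_dict())
        deltas_low.append(cost_delta(predicted, actual, n_tr, catalog, "low"))
        deltas_high.append(cost_delta(predicted, actual, n_tr, catalog, "high"))
    cost_summary = pd.DataFrame({
        "tariff": ["low", "high"],
        "mean_delta": [float(np.mean(deltas_low)) if deltas_low else np.nan,
                       float(np.mean(deltas_high)) if deltas_high else np.nan],
        "n_patients": [len(deltas_low), len(deltas_high)],
    })

    # 6. severity-strata sensitivity --------------------------------------
    strata_rows = []
    severe, less_severe = sensitivity_strata(test_i)
    ref_label = ("machine_restricted" if "machine_restricted" in policy_months
                 else "machine")
    comp_label = "guideline1" if "guideline1" in policy_months else "random"
    for name, mask in (("severe", severe), ("less_severe", less_severe)):
        ids = mask[mask].index.intersection(policy_months.index)
        if len(ids) < 3:
            continue
        res = compare_policies(policy_months.loc[ids, ref_label],
                               policy_months.loc[ids, comp_label])
        strata_rows.append({
            "stratum": name, "n": len(ids),
            "comparison": f"{ref_label}_vs_{comp_label}",
            "mean_months_machine": float(policy_months.loc[ids, ref_label].mean()),
            "mean_months_comparator": float(policy_months.loc[ids, comp_label].mean()),
            "mean_difference": res.mean_difference,
            "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
            "p_value": res.p_value,
        })
    strata_tests = pd.DataFrame(strata_rows)

    manifest = {
        "version": _version,
        "global_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "n_patients": int(cohort.n_patients),
        "n_trials": int(len(cohort.trials)),
        "partition_sizes": {"train": train.n_patients, "validation": val.n_patients,
                            "test": test.n_patients},
        "classes": classes,
        "selected_kernels": selected,
        "policies": policies,
    }

    result = PipelineResult(
        cohort=cohort,
        partitions=partition_frame(train, val, test),
        ites=ites,
        pairwise_long=pairwise_long,
        effect_summary=effect_summary,
        heterogeneity_test=het_test,
        cv_accuracy=cv_accuracy,
        policy_months=policy_months,
        policy_tests=policy_tests,
        topk=topk,
        cost_summary=cost_summary,
        strata_tests=strata_tests,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, ground_truth, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, ground_truth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.cohort.save(outdir / "cohort")
    ground_truth.to_json(outdir / "cohort" / "ground_truth.json")
    result.partitions.to_csv(outdir / "partitions.csv", index=False)
    result.pairwise_long.to_csv(outdir / "pairwise_effects.csv", index=False)
    result.ites.to_csv(outdir / "ites.csv")
    result.effect_summary.to_csv(outdir / "effect_summary.csv")
    result.cv_accuracy.to_csv(outdir / "cv_accuracy.csv")
    result.policy_months.to_csv(outdir / "policy_months.csv",
                                index_label="patient_id")
    result.policy_tests.to_csv(outdir / "policy_tests.csv", index=False)
    result.cost_summary.to_csv(outdir / "cost_summary.csv", index=False)
    result.strata_tests.to_csv(outdir / "strata_tests.csv", index=False)
    het = result.heterogeneity_test
    summary = {
        "topk_coverage": {str(k): v for k, v in result.topk.items()},
        "heterogeneity_test": None if het is None else {
            "mean_difference": het.mean_difference,
            "ci_lower": het.ci_lower, "ci_upper": het.ci_upper,
            "p_value": het.p_value,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def run_reference_comparison() -> TestResult:
    """Conditional-vs-overall contrast recomputed from the shipped
    reference effect table (effects-stage-only mode)."""
    overall, conditional = reference_rate_vectors()
    return paired_difference_test(overall, conditional)
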