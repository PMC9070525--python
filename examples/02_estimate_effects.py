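"""Estimate individualized treatment effects end to end on a small cohort.

Runs the full chain — stratified 4:1/4:1 split, PPCA imputation fitted on
the training partition, pairwise causal multitask GP fits, per-class ITE
aggregation — and prints the out-of-sample effect summary: modelled ATE
(median, IQR of ITEs), conditional ATE (within the above-median subgroup),
and the observed response rates among triallers, followed by the
heterogeneity contrast across classes.
"""

from migrx import (KernelConfig, PipelineConfig, SplitSpec, SyntheticConfig,
                   run_pipeline)

config = PipelineConfig(
    synthetic=SyntheticConfig(
        n_patients=400, classes=("tca", "topiramate", "betablockers"),
        heterogeneity=1.0, missing_rate=0.03, seed=1),
    split=SplitSpec(seed=1),
    kernel_candidates=[KernelConfig(kernel="rbf", n_restarts=1, max_iter=50)],
    n_components=8,
    n_realizations=200,
    n_restarts=1,
    seed=1,
)
result = run_pipeline(config)

cols = ["ate_median", "ate_q1", "ate_q3", "cate_median",
        "overall_true", "conditional_true", "n_trialled"]
print("out-of-sample effect summary (test partition):")
print(result.effect_summary[cols].round(3).to_string())

het = result.heterogeneity_test
print(f"\nconditional vs overall true response rates across classes:")
print(f"  mean difference {het.mean_difference:.3f} "
      f"(95% CI {het.ci_lower:.3f} to {het.ci_upper:.3f}, p={het.p_value:.3f})")
print("A positive difference means patients the model singles out respond "
      "more often than the trialled population at large — evidence of "
      "heterogeneous responsiveness.")

print("\nper-class CV accuracy of response from the modelled ITE:")
print(result.cv_accuracy.round(3).to_string())
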