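# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `migrx`.

## The scientific setting

Preventative treatment of chronic migraine is sequential: classes of
preventatives (ten are modelled by default — onabotulinumtoxinA,
flunarizine, candesartan, SNRI, topiramate, tricyclic antidepressants,
acupuncture, valproate, betablockers, serotonergic agents) are trialled one
after another, a response being a ≥50% reduction in headache days over an
evaluation period of at least three months (six for onabotulinumtoxinA,
whose effect is adjudicated only after two injection cycles). Two linked
questions are addressed. First, is responsiveness *heterogeneous* — do
identifiable patients respond to specific classes — or does apparent
variability reduce to noise around class-level effects? Second, if
responsiveness is predictable, how much time in pain is saved by trialling
classes in the order of each patient's predicted response probability
("machine prescription") rather than by guideline, expert habit, chance or
cost?

Because the motivating clinical dataset is not public, the package pairs
the analysis with a synthetic cohort generator whose ground truth is known,
so every claim the analysis makes can be checked against the mechanism that
generated the data.

## Synthetic cohorts

Each patient has a latent severity factor `u ~ N(0,1)`. Continuous
features are `lam_j * u + sqrt(1 - lam_j^2) * eps`, binary features are
Bernoulli with logit linear in `u`, and the two severity fields are clipped
rounded Gaussians tied to `u` (headache days/month centred near 25 with SD
≈ 7.6, bounded [0, 31]; exacerbation intensity centred near 8.2 with SD ≈
1.3 on the 0–10 scale), so the severity strata used in the sensitivity
analysis (≥25 days and intensity ≥9 versus <25 and <9) are both populated.

The true response model for class `c` is logistic:

    p_c(x) = sigmoid(alpha_c + h * (beta + gamma_c) . x)

with a shared prognostic vector `beta` (entries `N(0, 0.8^2/d)`), a
class-specific interaction vector `gamma_c` (entries `N(0, 1/d)`), and the
single heterogeneity scale `h`. At `h = 0` every patient has the identical
per-class probability `sigmoid(alpha_c)` — the null world in which the
conditional-subgroup contrast must vanish. The intercepts `alpha_c` are
calibrated by root-finding so the cohort-mean response probability matches
the per-class baseline targets (by default the published overall response
rates, 0.14–0.64). The coefficient scales were fixed once at values giving
roughly one logit-SD of individual signal at `h = 1` — enough spread that
the true pairwise effects have SD ≈ 0.15–0.2 on the probability scale,
a realistic regime in which modelling is useful but far from trivial.

Allocation is confounded: each patient trials `k` distinct classes, `k`
drawn from a pmf whose quartiles are 2/4/6 (matching the reported
trialling distribution), chosen by Gumbel-top-k sampling over softmax
logits `confounding * delta_c . x`. Responses are independent Bernoulli
draws from `p_c(x)`. Missingness is completely at random (the source
cohort's mechanism is uncharacterized); patients with more than 10% of
features masked are dropped, mirroring the original exclusion rule, and
the generator caps the nominal rate at 10%.

## Preprocessing

The cohort is split 4:1 into (train+validation) : test and the former 4:1
again, stratified on a binned trialled-class count and an any-response
indicator (the stratification keys are not specified in the source; these
preserve outcome balance). Integer partition sizes follow
largest-remainder rounding, so n = 1000 yields exactly 640/160/200.
Strata with fewer than three members fall back to a pooled remainder with
a warning.

Missing features are imputed with probabilistic PCA (`x = mu + W z + eps`,
isotropic residual), fitted by exact EM over both the latent factors and
the missing cells on internally standardized training data; the
observed-data log-likelihood is non-decreasing by construction and is
monitored (tolerance 1e-6 relative change, at most 500 iterations; default
10 components). Transforming any table fills missing cells with posterior
means, standardizes continuous features with *training* statistics, and
thresholds binary features at 0.5 on the original scale — imputation is a
single continuous model, with binarization only at the output. No
statistic of validation or test data enters the imputer or scaler.

## Pairwise causal multitask GP

For an ordered pair (A, B), all trials of A (arm 1) and B (arm 0) form a
two-arm observational dataset; a patient who trialled both contributes one
row per arm (within-patient correlation is not modelled — the simplest
defensible choice). The two potential-outcome surfaces are modelled
jointly as a multitask GP with intrinsic-coregionalization covariance

    cov(f_w(x), f_w'(x')) = B[w, w'] * k(x, x'),

where `k` is a unit-variance RBF or Matérn-5/2 kernel (optionally ARD) and
`B = L L^T` is a free 2×2 PSD task covariance holding the signal
variances; each arm has its own Gaussian noise variance, and each arm's
constant mean (its training response rate) is subtracted before fitting.
Binary outcomes are treated as real-valued on {0, 1} and the posterior
mean is read as a response probability; this keeps the effect on the same
scale as observed response rates (a probit/logit likelihood would need
approximate inference and is out of scope). Hyperparameters maximize the
log marginal likelihood via L-BFGS with analytic gradients, log-transformed
positive parameters, bounds ±12 in log space, a median-distance lengthscale
initialization and multi-restart (default 5; the large simulation studies
use 1 restart with the same initialization, which we found sufficient at
their data sizes). The correlation between arms encoded in `B` is what
lets confounded, partially-overlapping arms inform each other; with `B`
constrained diagonal the model provably decouples into two independent
single-output GPs, which the tests verify against scikit-learn's GP as an
external oracle.

The pairwise ITE is `tau_AB(x) = m_1(x) - m_0(x)`, predicted for every
patient of a partition, trialled or not. Kernel families are compared by
discounted cumulative gain on validation data: patients with an observed
response for an arm are ranked by the predicted effect signed toward that
arm, and `DCG = sum_i rel_i / log2(i+1)` is summed over the two arms; the
candidate with the highest validation DCG wins, ties going to list order.
The plain `rel/log2(i+1)` DCG is a documented package choice. After
selection the winner is refitted on train+validation and evaluated on the
held-out test partition only.

## Effects and the heterogeneity contrast

A patient's per-class ITE is the arithmetic mean of all signed pairwise
effects involving that class (9 terms for 10 classes, each of the 45 pair
models contributing to two classes); the class is undefined for a patient
unless every pair produced a prediction. The modelled ATE is the median
(IQR) of ITEs — medians because the ITE distributions are skewed — and the
conditional subgroup is the set of patients with ITE *strictly above* the
class median within the evaluated partition (the median patient is
excluded; with continuous ITEs ties are measure-zero). True treatment
effects are observed response rates among patients who actually trialled
the class; conditional true rates use only subgroup members who trialled
it, since response is otherwise unobserved.

The central inference is a one-sample two-sided t-test of the per-class
differences (conditional minus overall true rate) with a 95% CI on k-1
degrees of freedom. Validity of the ITEs as predictors is quantified by
10-fold cross-validated accuracy of a single-predictor logistic regression
(ITE → response) at the 0.5 threshold, with seeded fold assignment and
single-class training folds skipped. Prescriptive-policy tests use a
Bonferroni-corrected level of 0.05/14 ≈ 0.004; the effect analysis uses
0.05. A reporting helper chooses mean/SD versus median/IQR by a
Shapiro-Wilk test at 0.05.

Because the ITEs are means of pairwise probability differences, they can
stray outside [0, 1]; they are clipped only where a probability is needed
(the policy model clamps to [0.01, 0.99], which leaves the realistic
0.06–0.44 effect range untouched).

## Impact model

With per-patient success probabilities `p_1..p_n` in trial order, the
first-success pmf is `P{X=k} = prod_{i<=k}(1-p_i) * p_{k+1}` and the
residual failure mass is `prod_i (1-p_i)`; their sum is exactly one, which
the tests enforce at 1e-12 against brute-force enumeration of all `2^n`
outcome paths. Expected months-to-response is `sum_k P{X=k} T_k` with
`T_k` the cumulative evaluation duration through trial k+1 — the general
form is needed because onabotulinumtoxinA evaluates over 6 months, and it
reduces exactly to the homogeneous-duration `(k+1) t P{X=k}` form
otherwise. Both the unconditional expectation and the expectation
conditional on eventual success (divided by one minus the residual) are
computed; the conditional variant is the headline, because the residual
mass of poor responders otherwise deflates their expected time. With
equal durations, ordering by descending probability minimizes the
conditional expectation — verified exhaustively over all 120 permutations
of five treatments.

Machine prescription ranks each patient's classes by descending ITE (ties
alphabetical); the restricted variant pins onabotulinumtoxinA to the
fourth trial to neutralize its longer evaluation period. Comparators
follow the published constructions: guideline 1 draws three of the seven
evidence-based oral preventives then onabotulinumtoxinA; guideline 2 draws
two of {betablockers, candesartan, TCA, SNRI}, one of {topiramate,
valproate, flunarizine}, then onabotulinumtoxinA; the NICE sequence
permutes {betablockers, topiramate, TCA} then onabotulinumtoxinA; the
expert order is configurable (the surveyed expert aggregate is not public
— the shipped default is a synthetic placeholder following the published
effect-size rank); cost-ordered sorts by tariff; random permutes the whole
catalog. Randomized policies are averaged over seeded Monte-Carlo
realization sets (default 1000, matching the published random-policy
count) rather than a single draw, for variance control. Policy
distributions are compared with a two-tailed Welch t-test. Tariffs are
per-trial configuration inputs (the shipped defaults are synthetic
placeholders on a plausible pound scale); the cost delta for a patient is
the sum of the first n predicted trials minus the sum of their n actual
trials (negative = machine cheaper).

## Validation studies

The bundled studies (`migrx.studies`) define the package's standing
experiments; their problem sizes were chosen to finish in minutes on one
core while retaining power.

- *Pairwise recovery*: two classes, 800 patients trialling exactly one
  class each under confounded allocation, heterogeneity 1. Median Pearson
  correlation between predicted and true pairwise effects across three
  seeds is required to reach 0.5 (observed ≈ 0.7), and PEHE (RMSE between
  estimated and true pairwise effect) must fall monotonically as the
  training subset grows through 100/300/800 rows.
- *Heterogeneity detection*: four classes with spread baselines, 1000
  patients, full split/impute/fit chain, ITEs on the held-out test
  partition only. Pooling per-class contrasts over three seeds, the mean
  conditional-minus-overall difference must be positive (p < 0.05) at
  heterogeneity 1 and lie within three standard errors of zero at
  heterogeneity 0 with the same seeds.
- *Policy benefit*: the machine ordering from the heterogeneous run is
  scored against the random policy with months computed under the
  *ground-truth* probabilities, so the comparison cannot be won by
  construction; machine must be faster at p < 0.004. With homogeneous
  probabilities and equal durations the two policies coincide exactly.

What passing these studies does *not* show: the generator draws responses
from the same logistic family the intercept calibration assumes, its
missingness is purely random, allocation confounding is linear-softmax,
and trials are independent within patient. Real clinical data violate all
four; results on synthetic cohorts bound what the pipeline can do under
its own assumptions, not its field performance.

## Numerical choices and degenerate inputs

- GP jitter 1e-8 on the covariance diagonal; failed Cholesky during
  optimization returns a large objective value rather than aborting the
  restart loop; an all-restarts failure raises with diagnostics.
- Pair datasets require 20 rows per arm by default (in the spirit of the
  source cohort's at-least-100-trials inclusion rule, scaled to synthetic
  sizes).
- The paired t-test refuses zero-variance differences; the conditional
  expectation refuses all-zero success probabilities; empty DCG input,
  all-missing feature columns, unseen feature columns, unknown classes and
  unknown policy labels all raise with the offending name.
- All randomness flows from integer seeds through `numpy` `SeedSequence`
  substreams; the pipeline derives per-stage seeds from one global seed,
  and repeated runs are byte-identical.

## Known limitations

- Gaussian likelihood on binary outcomes: posterior means are not strictly
  confined to [0, 1] (clamped only where probabilities are required); no
  credible intervals on tau are exposed.
- Exact GP inference is O(n^3): adequate for cohort-scale pair datasets
  (hundreds to a few thousand rows), not for biobank scale.
- The conditional-subgroup median is computed within the evaluated
  partition (whether the original analysis used the full-cohort median is
  not stated).
- The expert order and the tariff table are placeholders; conclusions
  involving them are illustrative until real values are configured.
- Sequential-trialling independence: the impact model ignores carry-over,
  dropout, adverse events and dose titration.
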