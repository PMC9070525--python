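"""Per-class effect aggregation, subgroup contrasts and validation.

A patient's individualized treatment effect (ITE) for class ``c`` is the mean
of the signed pairwise effects of every pair containing ``c``.  Population
summaries follow the reporting conventions of the analysis: the modelled
average treatment effect (ATE) is the median (IQR) of ITEs; the *conditional*
subgroup of a class is the set of patients whose ITE lies strictly above the
class median; "true" treatment effects are observed response rates among the
patients who actually trialled the class.  The central heterogeneity contrast
compares conditional vs overall true rates across classes with a one-sample
t-test of the differences.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .synthetic import CohortTable

__all__ = [
    "TestResult",
    "AnalysisConfig",
    "aggregate_class_ite",
    "conditional_subgroup",
    "summarize_effects",
    "paired_difference_test",
    "cv_validation_accuracy",
    "describe_distribution",
    "load_reference_effects",
    "reference_rate_vectors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """Mean difference with a 95% CI and a two-sided p-value."""

    mean_difference: float
    ci_lower: float
    ci_upper: float
    p_value: float
    df: float
    statistic: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.mean_difference <= self.ci_upper):
            raise ValueError("confidence interval must bracket the mean difference")


@dataclass(frozen=True)
class AnalysisConfig:
    """Significance levels and the conditional-subgroup rule.

    The prescriptive analyses use a Bonferroni-corrected level for 14
    comparisons; the treatment-effect analysis uses the conventional 0.05.
    """

    n_policy_comparisons: int = 14
    alpha_ite: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha_ite < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_policy_comparisons < 1:
            raise ValueError("n_policy_comparisons must be positive")

    @property
    def alpha_prescriptive(self) -> float:
        """0.05 Bonferroni-corrected for the prescriptive comparisons."""
        return 0.05 / self.n_policy_comparisons


# ---------------------------------------------------------------------------
# ITE aggregation
# ---------------------------------------------------------------------------

def aggregate_class_ite(
    pairwise: Mapping[tuple[str, str], pd.Series],
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-patient per-class ITE as the mean of signed pairwise effects.

    ``pairwise`` maps (class_a, class_b) to a per-patient Series of effects
    signed toward ``class_a``; each pair contributes +tau to its first class
    and -tau to its second.  A class's ITE is defined for a patient only when
    every pair involving that class produced a prediction for them; undefined
    entries are NaN.
    """
    if classes is None:
        classes = sorted({c for pair in pairwise for c in pair})
    classes = list(classes)
    index = None
    for s in pairwise.values():
        index = s.index if index is None else index.union(s.index)
    if index is None:
        raise ValueError("no pairwise effects supplied")

    out = {}
    expected = len(classes) - 1
    for c in classes:
        terms = []
        for (a, b), s in pairwise.items():
            if c == a:
                terms.append(s.reindex(index))
            elif c == b:
                terms.append(-s.reindex(index))
        if len(terms) != expected:
            logger.warning(
                "class %s has %d of %d pair models; ITE undefined where missing",
                c, len(terms), expected,
            )
        if len(terms) != expected:
            out[c] = pd.Series(np.nan, index=index)
            continue
        stacked = pd.concat(terms, axis=1)
        vals = stacked.mean(axis=1)
        vals[stacked.isna().any(axis=1)] = np.nan
        out[c] = vals
    ites = pd.DataFrame(out, index=index)
    ites.index.name = "patient_id"
    if not np.isfinite(ites.to_numpy()[~np.isnan(ites.to_numpy())]).all():
        raise ValueError("non-finite ITE encountered")
    return ites


def conditional_subgroup(ites: pd.DataFrame | pd.Series, class_name: str | None = None) -> pd.Series:
    """Boolean mask of patients with ITE *strictly above* the class median.

    The median patient itself is excluded (above-median read literally); with
    continuous effects ties are measure-zero.
    """
    col = ites[class_name] if isinstance(ites, pd.DataFrame) else ites
    valid = col.dropna()
    if valid.empty:
        raise ValueError("ITE undefined for every patient")
    med = valid.median()
    mask = col > med
    return mask.fillna(False)


def summarize_effects(
    ites: pd.DataFrame,
    cohort: CohortTable,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-class effect summary over the patients in ``ites``.

    Columns: modelled ATE median/IQR, modelled conditional ATE median/IQR,
    overall and conditional true response rates (among patients who trialled
    the class), and the trialled counts.  Classes with no trialled patients
    get NaN true rates and a warning flag in ``true_rates_defined``.
    """
    classes = list(classes) if classes is not None else list(ites.columns)
    rows = []
    for c in classes:
        col = ites[c].dropna()
        if col.empty:
            raise ValueError(f"no ITEs defined for class {c!r}")
        q1, med, q3 = col.quantile([0.25, 0.5, 0.75])
        mask = conditional_subgroup(ites, c)
        cond = col[mask.reindex(col.index, fill_value=False)]
        cq1, cmed, cq3 = (cond.quantile([0.25, 0.5, 0.75])
                          if not cond.empty else (np.nan,) * 3)

        resp = cohort.responses(c)
        resp = resp[~resp.index.duplicated(keep="first")]
        resp = resp[resp.index.isin(col.index)]
        n_trialled = len(resp)
        overall_true = resp.mean() if n_trialled else np.nan
        cond_resp = resp[resp.index.isin(cond.index)]
        cond_true = cond_resp.mean() if len(cond_resp) else np.nan
        if n_trialled == 0:
            warnings.warn(f"class {c!r} has no trialled patients in this partition",
                          UserWarning, stacklevel=2)
        rows.append({
            "class_name": c,
            "ate_median": med, "ate_q1": q1, "ate_q3": q3,
            "cate_median": cmed, "cate_q1": cq1, "cate_q3": cq3,
            "overall_true": overall_true,
            "conditional_true": cond_true,
            "n_trialled": n_trialled,
            "n_trialled_conditional": len(cond_resp),
            "true_rates_defined": n_trialled > 0,
        })
    return pd.DataFrame(rows).set_index("class_name")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def paired_difference_test(
    overall_rates: Sequence[float], conditional_rates: Sequence[float]
) -> TestResult:
    """One-sample two-sided t-test on (conditional - overall) across classes.

    The 95% CI uses the t quantile with k-1 degrees of freedom.  Zero
    variance of the differences leaves the statistic undefined and raises.
    """
    a = np.asarray(overall_rates, dtype=float)
    b = np.asarray(conditional_rates, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of at least two classes")
    d = b - a
    if np.allclose(d.var(ddof=1), 0.0):
        raise ValueError("zero variance of differences; t statistic undefined")
    k = len(d)
    mean = d.mean()
    se = d.std(ddof=1) / np.sqrt(k)
    t = mean / se
    df = k - 1
    p = 2 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.975, df)
    return TestResult(mean_difference=float(mean),
                      ci_lower=float(mean - crit * se),
                      ci_upper=float(mean + crit * se),
                      p_value=float(p), df=float(df), statistic=float(t))


def cv_validation_accuracy(
    ites: Sequence[float],
    responses: Sequence[int],
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """K-fold CV accuracy of a one-predictor logistic model (ITE -> response).

    Folds are assigned by a seeded shuffle; a training fold containing a
    single response level is skipped with a warning.  Returns (mean, sd) of
    the per-fold accuracies at the 0.5 threshold.
    """
    x = np.asarray(ites, dtype=float).reshape(-1, 1)
    y = np.asarray(responses, dtype=int)
    if len(x) < folds:
        raise ValueError("need at least as many observations as folds")
    if len(np.unique(y)) < 2:
        raise ValueError("both response levels must be present")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in kf.split(x):
        if len(np.unique(y[train_idx])) < 2:
            warnings.warn("single-class training fold skipped", UserWarning,
                          stacklevel=2)
            continue
        clf = LogisticRegression(C=1e6, solver="lbfgs")
        clf.fit(x[train_idx], y[train_idx])
        accs.append(float((clf.predict(x[test_idx]) == y[test_idx]).mean()))
    if not accs:
        raise ValueError("no usable folds")
    return float(np.mean(accs)), float(np.std(accs, ddof=0))


def describe_distribution(values: Sequence[float], alpha: float = 0.05) -> dict:
    """Reporting helper: mean/SD under normality, median/IQR otherwise.

    Normality is judged by the Shapiro-Wilk test at ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("need at least three observations")
    stat, p = stats.shapiro(x)
    if p >= alpha:
        return {"normal": True, "location": float(x.mean()),
                "spread": float(x.std(ddof=1)), "labels": ("mean", "sd"),
                "shapiro_p": float(p)}
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return {"normal": False, "location": float(med),
            "spread": (float(q1), float(q3)), "labels": ("median", "iqr"),
            "shapiro_p": float(p)}


# ---------------------------------------------------------------------------
# Reference effect table
# ---------------------------------------------------------------------------

def load_reference_effects() -> pd.DataFrame:
    """The published per-class effect table shipped with the package.

    Ten preventative classes with modelled ATE/conditional-ATE medians and
    IQRs, overall and conditional true response rates, and per-class CV
    accuracies, as printed in the source report.
    """
    ref = importlib.resources.files("migrx.data") / "reference_effects.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if len(df) != 10:
        raise ValueError("malformed reference effect table")
    return df.set_index("class_name")


def reference_rate_vectors() -> tuple[np.ndarray, np.ndarray]:
    """(overall, conditional) true-rate vectors from the reference table."""
    df = load_reference_effects()
    return df["overall_true"].to_numpy(), df["conditional_true"].to_numpy()
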