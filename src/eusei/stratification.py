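"""Patient-level risk stratification statistics.

GISTs are risk-stratified by the NIH consensus classification (very low /
low / intermediate / high, from tumor size and mitotic count).  For binary
malignant-potential analysis the four categories collapse to low-risk
(very low + low) vs high-risk (intermediate + high).  The elasticity index
is *negatively* oriented: stiffer (smaller) values indicate higher
malignant potential, so a patient is called high-risk when the value falls
strictly below the operating cutoff.

This module provides the grouping rule, ROC analysis with Youden-index
cutoff selection, diagnostic metrics with proportion confidence intervals,
Spearman correlation, logistic odds ratios, and cohort summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidArgumentError, SeparationError, UngroupableError

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"

NIH_CATEGORIES = ("very_low", "low", "intermediate", "high")
_NIH_GROUP = {
    "very_low": LOW_RISK,
    "low": LOW_RISK,
    "intermediate": HIGH_RISK,
    "high": HIGH_RISK,
}


def group_nih(nih: str) -> str:
    """Collapse an NIH risk category to the binary malignant-potential group.

    very_low / low -> low_risk; intermediate / high -> high_risk.  Unknown
    categories are ungroupable and must be excluded (with a log entry) by
    the caller.
    """
    key = str(nih).strip().lower()
    if key not in _NIH_GROUP:
        raise UngroupableError(f"NIH category {nih!r} cannot be grouped")
    return _NIH_GROUP[key]


def classify(eus_e_ai: float, cutoff: float) -> str:
    """Classify one elasticity value at a cutoff: strictly below -> high_risk."""
    if eus_e_ai is None or (isinstance(eus_e_ai, float) and math.isnan(eus_e_ai)):
        raise InvalidArgumentError("missing elasticity value is unclassifiable")
    if not (0 <= eus_e_ai <= 1 and 0 <= cutoff <= 1):
        raise InvalidArgumentError("value and cutoff must lie in [0, 1]")
    return HIGH_RISK if eus_e_ai < cutoff else LOW_RISK


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with high-risk malignant potential as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidArgumentError("confusion counts must be non-negative")
        if self.n < 1:
            raise InvalidArgumentError("confusion matrix must hold >= 1 case")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype == bool:
        return lab
    return lab == HIGH_RISK


def confusion(
    values: Sequence[float], labels: Sequence, cutoff: float
) -> ConfusionMatrix:
    """Count the confusion matrix of the cutoff rule against true groups."""
    v = np.asarray(values, dtype=float)
    y = _as_binary_labels(labels)
    if v.shape != y.shape:
        raise InvalidArgumentError("values and labels differ in length")
    if np.isnan(v).any():
        raise InvalidArgumentError("missing values are unclassifiable")
    pred = v < cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


@dataclass(frozen=True)
class MetricCI:
    """Point estimate with a 95% CI, all on the percent scale."""

    estimate: float
    lower: float
    upper: float


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: MetricCI | None
    specificity: MetricCI | None
    ppv: MetricCI | None
    npv: MetricCI | None
    accuracy: MetricCI | None
    cutoff: float | None = None
    ci_method: str = "wald"


def _proportion_ci(k: int, n: int, method: str) -> MetricCI:
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise InvalidArgumentError("ci_method must be 'wald' or 'wilson'")
    lo, hi = proportion_confint(k, n, alpha=0.05, method=sm_method)
    return MetricCI(
        estimate=100.0 * k / n,
        lower=float(np.clip(lo * 100.0, 0.0, 100.0)),
        upper=float(np.clip(hi * 100.0, 0.0, 100.0)),
    )


def diagnostic_metrics(
    cm: ConfusionMatrix, ci_method: str = "wald", cutoff: float | None = None
) -> DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV/accuracy with 95% CIs (percent scale).

    The default interval is Wald ``p +/- 1.96 sqrt(p(1-p)/n)`` clamped to
    [0, 100]; Wilson is available by flag.  A metric whose denominator is
    zero is reported as None (undefined), never as 0.
    """

    def metric(k: int, n: int) -> MetricCI | None:
        return _proportion_ci(k, n, ci_method) if n > 0 else None

    return DiagnosticSummary(
        sensitivity=metric(cm.tp, cm.tp + cm.fn),
        specificity=metric(cm.tn, cm.tn + cm.fp),
        ppv=metric(cm.tp, cm.tp + cm.fp),
        npv=metric(cm.tn, cm.tn + cm.fn),
        accuracy=metric(cm.tp + cm.tn, cm.n),
        cutoff=cutoff,
        ci_method=ci_method,
    )


@dataclass(frozen=True)
class RocCurve:
    """ROC curve over candidate cutoffs, with trapezoidal AUC.

    ``points`` rows are (cutoff, sensitivity, specificity).  The score is
    negatively oriented: sensitivity at cutoff c is the fraction of
    high-risk patients with value strictly below c.
    """

    points: np.ndarray  # (m, 3)
    auc: float

    @property
    def cutoffs(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def sensitivities(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def specificities(self) -> np.ndarray:
        return self.points[:, 2]


def roc(values: Sequence[float], labels: Sequence) -> RocCurve:
    """ROC analysis of a negatively oriented score against binary groups.

    Candidate cutoffs are the midpoints between consecutive distinct sorted
    values plus -inf/+inf sentinels; the AUC is the trapezoidal area over
    (1 - specificity, sensitivity).
    """
    v = np.asarray(values, dtype=float)
    y = _as_binary_labels(labels)
    if v.shape != y.shape:
        raise InvalidArgumentError("values and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("ROC needs both classes present")
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    pos, neg = v[y], v[~y]
    sens = np.array([(pos < c).mean() for c in cutoffs])
    spec = np.array([(neg >= c).mean() for c in cutoffs])
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocCurve(points=np.column_stack([cutoffs, sens, spec]), auc=auc)


def youden_cutoff(curve: RocCurve) -> tuple[float, float]:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Ties resolve toward higher sensitivity, then toward the lower cutoff.
    """
    J = curve.sensitivities + curve.specificities - 1.0
    best = None
    for c, s, j in zip(curve.cutoffs, curve.sensitivities, J):
        key = (-j, -s, c)
        if best is None or key < best[0]:
            best = (key, c, j)
    return float(best[1]), float(best[2])


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidArgumentError("spearman needs equal-length inputs, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise InvalidArgumentError("spearman undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def _check_separation(x: np.ndarray, y: np.ndarray, name: str) -> None:
    x1, x0 = x[y == 1], x[y == 0]
    if x1.min() > x0.max() or x1.max() < x0.min():
        raise SeparationError(name)


def logistic_or(design: pd.DataFrame, outcome: Sequence) -> pd.DataFrame:
    """Univariable and multivariable logistic odds ratios with Wald 95% CIs.

    ``design`` holds numeric covariate columns; ``outcome`` the binary group
    (high_risk positive).  Complete separation is detected per covariate and
    reported by name rather than producing a divergent fit.  Returns a
    DataFrame indexed by covariate with columns
    ``or_uni, ci_low_uni, ci_high_uni, p_uni, or_multi, ci_low_multi,
    ci_high_multi, p_multi``.
    """
    import statsmodels.api as sm

    y = _as_binary_labels(outcome).astype(int)
    if y.min() == y.max():
        raise SeparationError("outcome")
    X = design.astype(float)
    if len(X) != len(y):
        raise InvalidArgumentError("design and outcome differ in length")
    for col in X.columns:
        _check_separation(X[col].to_numpy(), y, col)

    def fit(cols: list[str]) -> pd.DataFrame:
        exog = sm.add_constant(X[cols], has_constant="add")
        res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        ci = res.conf_int()
        out = pd.DataFrame(
            {
                "or": np.exp(res.params),
                "ci_low": np.exp(ci[0]),
                "ci_high": np.exp(ci[1]),
                "p": res.pvalues,
            }
        )
        return out.drop(index="const")

    uni = pd.concat([fit([c]) for c in X.columns])
    multi = fit(list(X.columns))
    table = uni.join(multi, lsuffix="_uni", rsuffix="_multi")
    table.columns = [
        "or_uni", "ci_low_uni", "ci_high_uni", "p_uni",
        "or_multi", "ci_low_multi", "ci_high_multi", "p_multi",
    ]
    table.index.name = "variable"
    return table


def format_count_percent(k: int, n: int) -> str:
    """Table-1 style count string, e.g. ``108 (57.1%)``."""
    return f"{k} ({100.0 * k / n:.1f}%)"


def cohort_summary(
    records: pd.DataFrame,
    group_col: str = "group",
    categorical: Sequence[str] = ("sex", "size_class", "location"),
    normal: Sequence[str] = ("age",),
    nonnormal: Sequence[str] = ("eus_e_ai",),
) -> dict:
    """Baseline-characteristics summary with between-group tests.

    Categorical variables report ``n (pct%)`` per level with a chi-square
    test (Fisher's exact for 2x2 tables with an expected count below 5);
    normally distributed continuous variables report mean (SD) with a
    t test, non-normal ones median [IQR] with a Mann-Whitney U test.
    Group comparison is skipped when fewer than two groups are present.
    """
    if len(records) < 1:
        raise InvalidArgumentError("need at least one record")
    out: dict = {"n": int(len(records))}
    groups = (
        [g for g, _ in records.groupby(group_col)] if group_col in records else []
    )
    two_groups = len(groups) == 2

    for col in categorical:
        if col not in records:
            continue
        entry: dict = {"overall": {}}
        counts = records[col].value_counts()
        for level, k in counts.items():
            entry["overall"][str(level)] = format_count_percent(int(k), len(records))
        if two_groups:
            tab = pd.crosstab(records[col], records[group_col])
            expected = stats.contingency.expected_freq(tab.to_numpy())
            if tab.shape == (2, 2) and expected.min() < 5:
                entry["p"] = float(stats.fisher_exact(tab.to_numpy())[1])
                entry["test"] = "fisher"
            else:
                entry["p"] = float(stats.chi2_contingency(tab.to_numpy())[1])
                entry["test"] = "chi2"
        out[col] = entry

    for col in normal:
        if col not in records:
            continue
        x = records[col].dropna()
        entry = {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0}
        if two_groups:
            a, b = (records.loc[records[group_col] == g, col].dropna() for g in groups)
            if len(a) > 1 and len(b) > 1:
                entry["p"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                entry["test"] = "t"
        out[col] = entry

    for col in nonnormal:
        if col not in records:
            continue
        x = records[col].dropna()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        entry = {"median": float(med), "q1": float(q1), "q3": float(q3)}
        if two_groups:
            a, b = (records.loc[records[group_col] == g, col].dropna() for g in groups)
            if len(a) > 0 and len(b) > 0:
                entry["p"] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                entry["test"] = "mannwhitney"
        out[col] = entry
    return out
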