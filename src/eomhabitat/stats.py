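"""Cohort statistics for treatment-response evaluation.

Continuous features are compared between the responsive and unresponsive
groups with Student's t-test when the Shapiro-Wilk test accepts normality
(p >= 0.05) in every group, and with the Mann-Whitney U test otherwise;
categorical tables use Pearson's chi-square. Measurement reproducibility is
quantified with ICC(2,1) (two-way random effects, absolute agreement,
single measure). Correlations use Pearson or Spearman under the same
normality gate, with |r| bands poor (<0.40), moderate [0.40, 0.60),
good [0.60, 0.80) and excellent (>=0.80). Candidate response markers are
combined by unpenalized binary logistic regression, and each score is
evaluated by ROC analysis: trapezoidal AUC (equivalently the concordance
fraction with half credit for ties), a DeLong 95% CI, and the observed-score
cutoff maximizing the Youden index (sensitivity + specificity - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm

__all__ = [
    "GroupComparisonResult",
    "IccResult",
    "CorrelationResult",
    "RocResult",
    "LogisticModel",
    "normality_gate",
    "compare_feature",
    "chi_square",
    "icc",
    "correlate",
    "correlation_band",
    "fit_logistic",
    "roc_analysis",
    "evaluate_response_markers",
]

ALPHA_NORMALITY = 0.05
POSITIVE_LABEL = "responsive"


@dataclass(frozen=True)
class GroupComparisonResult:
    feature_name: str
    test_used: Literal["t_test", "mann_whitney", "chi_square"]
    statistic: float
    p_value: float
    group_summaries: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model_descriptor: str = "ICC(2,1) two-way random, absolute agreement, single measure"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    method: Literal["pearson", "spearman"]
    band: Literal["poor", "moderate", "good", "excellent"]


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float | None
    direction: Literal["greater_is_positive", "lesser_is_positive"]
    sensitivity: float  # percent
    specificity: float  # percent
    p_value: float | None = None

    @property
    def cutoff_operator(self) -> str:
        return ">" if self.direction == "greater_is_positive" else "<="


@dataclass
class LogisticModel:
    feature_names: tuple[str, ...]
    coefficients: Mapping[str, float]
    p_values: Mapping[str, float]
    fitted_probabilities: np.ndarray
    converged: bool = True
    separation_flagged: bool = False


def _shapiro_normal(x: np.ndarray) -> bool:
    """Shapiro-Wilk at alpha=0.05; constant samples route to non-normal."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(ss.shapiro(x).pvalue) >= ALPHA_NORMALITY


def normality_gate(values_by_group: Mapping[str, Sequence[float]]) -> Literal["t_test", "mann_whitney"]:
    """t-test iff Shapiro-Wilk accepts normality (p >= 0.05) in every group."""
    for name, values in values_by_group.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
        if not _shapiro_normal(arr):
            return "mann_whitney"
    return "t_test"


def _summaries(groups: Mapping[str, np.ndarray], parametric: bool) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for name, x in groups.items():
        if parametric:
            out[name] = {"n": int(x.size), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            out[name] = {"n": int(x.size), "median": float(med), "q1": float(q1), "q3": float(q3)}
    return out


def compare_feature(table: pd.DataFrame, feature_name: str, group_col: str = "response") -> GroupComparisonResult:
    """Normality-gated two-group comparison of one feature column.

    Missing values (NaN delta% rows where the pre value was zero) are
    excluded pairwise, i.e. only for this feature.
    """
    if feature_name not in table.columns:
        raise KeyError(f"feature {feature_name!r} not in table")
    sub = table[[group_col, feature_name]].dropna()
    groups = {str(g): np.asarray(v[feature_name], dtype=float) for g, v in sub.groupby(group_col)}
    if len(groups) != 2 or any(v.size == 0 for v in groups.values()):
        raise ValueError(f"feature {feature_name!r}: need two non-empty groups after missingness exclusion")
    test = normality_gate(groups)
    a, b = (groups[k] for k in sorted(groups))
    if test == "t_test":
        res = ss.ttest_ind(a, b, equal_var=True)
    else:
        res = ss.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparisonResult(
        feature_name,
        test,
        float(res.statistic),
        float(res.pvalue),
        _summaries(groups, parametric=(test == "t_test")),
    )


def chi_square(contingency: np.ndarray, feature_name: str = "categorical") -> GroupComparisonResult:
    """Pearson chi-square (no continuity correction) on a 2 x K count table."""
    obs = np.asarray(contingency, dtype=float)
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("contingency counts must be non-negative with positive total")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = ss.chi2_contingency(obs, correction=False)
    return GroupComparisonResult(feature_name, "chi_square", float(res.statistic), float(res.pvalue))


def icc(measurements: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is an (n_subjects, k_raters) array; the 95% CI follows
    the standard F-based construction (McGraw & Wong case 2A).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("measurements must be (n_subjects, k>=2 ratings)")
    n, k = x.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)  # between subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # between raters
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    point = float((msr - mse) / denom)
    if mse == 0 and msc == 0:
        return IccResult(1.0, 1.0, 1.0)
    # F-based CI
    a = k * point / (n * (1.0 - point)) if point < 1.0 else np.inf
    b = 1.0 + k * point * (n - 1) / (n * (1.0 - point)) if point < 1.0 else np.inf
    if not np.isfinite(a):
        return IccResult(point, point, point)
    v = (a * msc + b * mse) ** 2 / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_low = ss.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = ss.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_up * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    return IccResult(point, float(min(lower, point)), float(max(upper, point)))


def correlation_band(r: float) -> str:
    """|r| interpretation bands: poor / moderate / good / excellent."""
    a = abs(r)
    if a < 0.40:
        return "poor"
    if a < 0.60:
        return "moderate"
    if a < 0.80:
        return "good"
    return "excellent"


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson if both variables pass the normality gate, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: correlation undefined")
    if _shapiro_normal(x) and _shapiro_normal(y):
        r, p = ss.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = ss.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(float(r), float(p), method, correlation_band(float(r)))


def fit_logistic(table: pd.DataFrame, feature_names: Sequence[str], label_col: str = "response") -> LogisticModel:
    """Unpenalized maximum-likelihood binary logistic regression.

    The fitted probability of the positive class ('responsive') per patient
    is the combined score used downstream. Perfect separation is flagged and
    the model reported as non-converged.
    """
    sub = table[list(feature_names) + [label_col]].dropna()
    if len(sub) < 10 * len(feature_names):
        raise ValueError("need at least 10 observations per feature")
    y = (sub[label_col] == POSITIVE_LABEL).astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("label column must contain both classes")
    X = sm.add_constant(sub[list(feature_names)].astype(float), has_constant="add")
    converged, separated = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            # singular designs (e.g. a constant feature) or perfect separation:
            # gradient methods still reach a maximizer of the likelihood
            separated = True
            fit = sm.Logit(y, X).fit(method="bfgs", disp=0, maxiter=500)
            converged = False
    params = dict(zip(X.columns, np.asarray(fit.params, dtype=float)))
    try:
        pvals = dict(zip(X.columns, np.asarray(fit.pvalues, dtype=float)))
    except Exception:
        pvals = {c: float("nan") for c in X.columns}
    probs = np.clip(np.asarray(fit.predict(X), dtype=float), 1e-12, 1 - 1e-12)
    return LogisticModel(tuple(feature_names), params, pvals, probs, converged, separated)


def _auc_concordance(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as P(pos > neg) + 0.5 P(pos = neg) via midranks (trapezoidal-equivalent)."""
    combined = np.concatenate([pos, neg])
    ranks = ss.rankdata(combined)
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _delong_se(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """Standard error of the AUC from DeLong structural components."""
    m, n = pos.size, neg.size
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return float(np.sqrt(max(var, 0.0)))


def _youden_scan(scores: np.ndarray, y: np.ndarray, direction: str) -> tuple[float, float, float]:
    """Best observed-score cutoff by Youden index; ties toward higher specificity.

    Returns (cutoff, sensitivity%, specificity%) under the convention
    positive iff score > cutoff (greater) or score <= cutoff (lesser).
    """
    pos, neg = scores[y == 1], scores[y == 0]
    candidates = np.unique(scores)
    best = None
    for c in candidates:
        if direction == "greater_is_positive":
            sens = np.mean(pos > c)
            spec = np.mean(neg <= c)
        else:
            sens = np.mean(pos <= c)
            spec = np.mean(neg > c)
        j = sens + spec - 1.0
        # tie-break: higher specificity, then the more conservative cutoff
        c_pref = c if direction == "greater_is_positive" else -c
        key = (j, spec, c_pref)
        if best is None or key > best[0]:
            best = (key, float(c), float(100 * sens), float(100 * spec))
    return best[1], best[2], best[3]


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int] | Sequence[str],
    direction: str = "auto",
    report_cutoff: bool = True,
) -> RocResult:
    """ROC of a score against a binary label.

    AUC is the concordance fraction with half credit for ties (equal to the
    trapezoidal area under the empirical ROC); the 95% CI uses DeLong's
    variance. With ``direction='auto'`` the orientation is chosen so that
    AUC >= 0.5. The reported cutoff is the observed score maximizing the
    Youden index; the positive call is 'score > cutoff' or 'score <= cutoff'
    depending on orientation, matching the reported direction operator.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        y = (labels == POSITIVE_LABEL).astype(int)
    else:
        y = labels.astype(int)
    keep = ~np.isnan(scores)
    scores, y = scores[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = scores[y == 1], scores[y == 0]
    auc_greater = _auc_concordance(pos, neg)
    if direction == "auto":
        direction = "greater_is_positive" if auc_greater >= 0.5 else "lesser_is_positive"
    elif direction not in ("greater_is_positive", "lesser_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    auc = auc_greater if direction == "greater_is_positive" else 1.0 - auc_greater
    se = _delong_se(pos, neg, auc)
    z975 = ss.norm.ppf(0.975)
    ci_low = float(np.clip(auc - z975 * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + z975 * se, 0.0, 1.0))
    p_value = float(2 * ss.norm.sf(abs(auc - 0.5) / se)) if se > 0 else (0.0 if auc != 0.5 else 1.0)
    if report_cutoff:
        cutoff, sens, spec = _youden_scan(scores, y, direction)
    else:
        cutoff, sens, spec = None, float("nan"), float("nan")
        _, sens, spec = _youden_scan(scores, y, direction)
    return RocResult(float(auc), ci_low, ci_high, cutoff, direction, sens, spec, p_value)


def evaluate_response_markers(
    table: pd.DataFrame,
    feature_names: Sequence[str] = ("dvol_LH", "dpct_volume_whole"),
    label_col: str = "response",
) -> pd.DataFrame:
    """ROC evaluation of each candidate marker and of their logistic combination.

    Returns a summary with one row per marker plus a 'combined' row:
    cutoff (with direction operator; '-' for the combined model, whose score
    is a fitted probability), AUC with 95% CI, sensitivity and specificity
    at the Youden-optimal point.
    """
    rows = []
    complete = table[list(feature_names) + [label_col]].dropna()
    for feat in feature_names:
        roc = roc_analysis(complete[feat], complete[label_col])
        rows.append(_roc_row(feat, roc, show_cutoff=True))
    model = fit_logistic(complete, feature_names, label_col)
    roc_comb = roc_analysis(model.fitted_probabilities, complete[label_col], report_cutoff=False)
    rows.append(_roc_row("combined", roc_comb, show_cutoff=False))
    return pd.DataFrame(rows)


def _roc_row(name: str, roc: RocResult, show_cutoff: bool) -> dict:
    return {
        "parameter": name,
        "cutoff": (f"{roc.cutoff_operator}{roc.cutoff:.6g}" if show_cutoff and roc.cutoff is not None else "-"),
        "auc": roc.auc,
        "ci_low": roc.ci_low,
        "ci_high": roc.ci_high,
        "sensitivity_pct": roc.sensitivity,
        "specificity_pct": roc.specificity,
        "p_value": roc.p_value,
    }
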