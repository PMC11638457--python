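"""Diagnostic-accuracy evaluation and paired-comparison statistics.

ROC/AUC with DeLong variance, Youden operating points, confusion-matrix
metrics with exact binomial intervals, McNemar and weighted generalized
score (Kosinski-style) paired tests, calibration tables, decision-curve
net benefit, and per-stratum AUC comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError

__all__ = [
    "ScoredCohort",
    "ConfusionMatrix",
    "MetricSet",
    "ComparisonResult",
    "mann_whitney_auc",
    "roc_auc",
    "youden_cutoff",
    "confusion_at",
    "metrics_with_ci",
    "percent_display",
    "delong_test",
    "unpaired_delong_test",
    "mcnemar_test",
    "kosinski_test",
    "calibration_bins",
    "net_benefit",
    "subgroup_auc",
    "load_reference_confusions",
]


# ---------------------------------------------------------------- containers


@dataclass
class ScoredCohort:
    scores: np.ndarray
    labels: np.ndarray
    ids: list[str] | None = None
    group: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise DomainError("scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise DomainError("labels must be binary 0/1")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be nonnegative")
        if self.total == 0:
            raise DomainError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    """Point estimates (fractions) with exact 95% binomial intervals.

    Undefined metrics (zero denominator) are ``nan`` with the name recorded
    in ``undefined``.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    ci: dict[str, tuple[float, float]]
    cutoff: float | None = None
    undefined: list[str] = field(default_factory=list)

    def as_percent(self) -> dict[str, int]:
        return {
            name: percent_display(getattr(self, name))
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
            if name not in self.undefined
        }


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    extra: dict = field(default_factory=dict)


# ----------------------------------------------------------------- ROC / AUC


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("AUC requires both classes present")


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(scores, labels):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    psi = gt + 0.5 * eq
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)


def roc_auc(cohort: ScoredCohort, alpha: float = 0.05):
    """ROC curve points and AUC with a DeLong-variance Wald interval.

    Returns ``(roc, auc, (lo, hi))`` where ``roc`` is an array of
    (threshold, sensitivity, specificity) rows, one per distinct score,
    under the call convention score >= threshold.
    """
    _check_two_classes(cohort.labels)
    scores, labels = cohort.scores, cohort.labels
    auc = mann_whitney_auc(scores, labels)
    v10, v01 = _delong_components(scores, labels)
    var = (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0) + (
        np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * np.sqrt(var))
    hi = min(1.0, auc + z * np.sqrt(var))
    thresholds = np.unique(scores)
    n1, n0 = labels.sum(), (1 - labels).sum()
    rows = []
    for t in thresholds:
        calls = scores >= t
        rows.append((t, (calls & (labels == 1)).sum() / n1,
                     (~calls & (labels == 0)).sum() / n0))
    return np.array(rows), auc, (float(lo), float(hi))


def youden_cutoff(cohort: ScoredCohort) -> float:
    """Observed-score threshold maximizing J = sens + spec - 1.

    Positive call iff score >= threshold; ties in J resolve to the higher
    (more specific) threshold.
    """
    rows, _, _ = roc_auc(cohort)
    j = rows[:, 1] + rows[:, 2] - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]
    return float(rows[best, 0])


def confusion_at(cohort: ScoredCohort, cutoff: float) -> ConfusionMatrix:
    """Counts with the positive-call convention score >= cutoff."""
    if not np.isfinite(cutoff):
        raise DomainError("cutoff must be finite")
    calls = cohort.scores >= cutoff
    pos = cohort.labels == 1
    return ConfusionMatrix(
        tp=int((calls & pos).sum()),
        fp=int((calls & ~pos).sum()),
        fn=int((~calls & pos).sum()),
        tn=int((~calls & ~pos).sum()),
    )


# ------------------------------------------------------------------- metrics


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def percent_display(fraction: float) -> int:
    """Integer percent, rounded half-up (97.5 -> 98)."""
    return int(np.floor(fraction * 100.0 + 0.5))


def metrics_with_ci(cm: ConfusionMatrix, cutoff: float | None = None,
                    alpha: float = 0.05) -> MetricSet:
    pieces = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "accuracy": (cm.tp + cm.tn, cm.total),
    }
    values, ci, undefined = {}, {}, []
    for name, (k, n) in pieces.items():
        if n == 0:
            values[name] = float("nan")
            ci[name] = (float("nan"), float("nan"))
            undefined.append(name)
        else:
            values[name] = k / n
            ci[name] = _clopper_pearson(k, n, alpha)
    return MetricSet(cutoff=cutoff, ci=ci, undefined=undefined, **values)


# -------------------------------------------------------------- paired tests


def delong_test(scores_a, scores_b, labels) -> ComparisonResult:
    """Paired DeLong test for the difference of two correlated AUCs."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise DomainError("paired test requires equal-length score vectors")
    _check_two_classes(labels)
    auc_a = mann_whitney_auc(scores_a, labels)
    auc_b = mann_whitney_auc(scores_b, labels)
    v10a, v01a = _delong_components(scores_a, labels)
    v10b, v01b = _delong_components(scores_b, labels)
    n1, n0 = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n0
    if var <= 0:
        return ComparisonResult(0.0, 1.0, "delong",
                                {"auc_a": auc_a, "auc_b": auc_b, "var": float(var)})
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(float(z), float(p), "delong",
                            {"auc_a": auc_a, "auc_b": auc_b, "var": float(var)})


def unpaired_delong_test(cohort_a: ScoredCohort, cohort_b: ScoredCohort) -> ComparisonResult:
    """Two-sample z-test on independent AUCs using DeLong variances."""
    out = []
    for c in (cohort_a, cohort_b):
        _check_two_classes(c.labels)
        auc = mann_whitney_auc(c.scores, c.labels)
        v10, v01 = _delong_components(c.scores, c.labels)
        var = (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0) + (
            np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0
        )
        out.append((auc, var))
    (a1, va), (a2, vb) = out
    var = va + vb
    if var <= 0:
        return ComparisonResult(0.0, 1.0, "delong_unpaired", {"auc_a": a1, "auc_b": a2})
    z = (a1 - a2) / np.sqrt(var)
    return ComparisonResult(float(z), float(2 * stats.norm.sf(abs(z))),
                            "delong_unpaired", {"auc_a": a1, "auc_b": a2})


def _metric_subset(calls_a, calls_b, labels, metric):
    calls_a = np.asarray(calls_a, int)
    calls_b = np.asarray(calls_b, int)
    labels = np.asarray(labels, int)
    if metric == "sensitivity":
        sel = labels == 1
        correct_a, correct_b = calls_a[sel] == 1, calls_b[sel] == 1
    elif metric == "specificity":
        sel = labels == 0
        correct_a, correct_b = calls_a[sel] == 0, calls_b[sel] == 0
    elif metric == "accuracy":
        correct_a, correct_b = calls_a == labels, calls_b == labels
    else:
        raise DomainError(f"unknown metric for McNemar: {metric!r}")
    return correct_a, correct_b


def mcnemar_test(calls_a, calls_b, labels, metric="accuracy",
                 exact_limit: int = 25) -> ComparisonResult:
    """McNemar's test on the discordant pairs of the metric's case subset.

    Exact binomial when b + c < ``exact_limit``, else chi-square with
    continuity correction.
    """
    correct_a, correct_b = _metric_subset(calls_a, calls_b, labels, metric)
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    n = b + c
    if n == 0:
        return ComparisonResult(0.0, 1.0, "mcnemar_exact", {"b": b, "c": c})
    if n < exact_limit:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return ComparisonResult(float(min(b, c)), float(p), "mcnemar_exact",
                                {"b": b, "c": c})
    chi2 = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return ComparisonResult(float(chi2), p, "mcnemar_chi2", {"b": b, "c": c})


def kosinski_test(calls_a, calls_b, labels, which="ppv") -> ComparisonResult:
    """Weighted generalized score test for paired predictive values.

    Marginal-regression formulation: every test-positive (for PPV; test-
    negative for NPV) subject-test record contributes outcome y and test
    indicator x; the efficient score for the test effect is evaluated at the
    pooled null estimate with a cluster-robust (subject-level) variance,
    giving a 1-df chi-square statistic.
    """
    calls_a = np.asarray(calls_a, int)
    calls_b = np.asarray(calls_b, int)
    labels = np.asarray(labels, int)
    if which == "ppv":
        in_a, in_b = calls_a == 1, calls_b == 1
        y = labels
    elif which == "npv":
        in_a, in_b = calls_a == 0, calls_b == 0
        y = 1 - labels
    else:
        raise DomainError(f"which must be 'ppv' or 'npv', got {which!r}")
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na == 0 or nb == 0:
        raise DegenerateInputError(
            f"{which} undefined: a test has no {'positive' if which == 'ppv' else 'negative'} calls"
        )
    # records: (x=0, y) for test A, (x=1, y) for test B
    ys = np.concatenate([y[in_a], y[in_b]])
    xs = np.concatenate([np.zeros(na), np.ones(nb)])
    clusters = np.concatenate([np.flatnonzero(in_a), np.flatnonzero(in_b)])
    p_bar = ys.mean()
    x_bar = xs.mean()
    resid = (xs - x_bar) * (ys - p_bar)
    u = resid.sum()
    cluster_sums = np.bincount(clusters, weights=resid)
    v = float(np.sum(cluster_sums**2))
    pv_a = y[in_a].mean()
    pv_b = y[in_b].mean()
    if v <= 0 or abs(u) < 1e-12:
        return ComparisonResult(0.0, 1.0, "kosinski_wgs",
                                {f"{which}_a": pv_a, f"{which}_b": pv_b})
    chi2 = u * u / v
    return ComparisonResult(float(chi2), float(stats.chi2.sf(chi2, df=1)),
                            "kosinski_wgs", {f"{which}_a": pv_a, f"{which}_b": pv_b})


# --------------------------------------------------- calibration / net benefit


def calibration_bins(cohort: ScoredCohort, n_bins: int = 10) -> list[dict]:
    """Equal-frequency calibration table (bin sizes differ by at most 1)."""
    if np.any((cohort.scores < 0) | (cohort.scores > 1)):
        raise DomainError("calibration requires scores in [0, 1]")
    n = cohort.scores.size
    if n < n_bins:
        warnings.warn(f"only {n} cases; reducing calibration bins to {n}")
        n_bins = max(1, n)
    order = np.argsort(cohort.scores, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, n_bins)):
        rows.append({
            "bin": b,
            "mean_predicted": float(cohort.scores[idx].mean()),
            "observed_rate": float(cohort.labels[idx].mean()),
            "n": int(idx.size),
        })
    return rows


def net_benefit(cohort: ScoredCohort, thresholds) -> list[dict]:
    """Decision-curve net benefit at each threshold probability."""
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise DomainError("thresholds must lie in (0, 1)")
    n = cohort.scores.size
    prevalence = cohort.labels.mean()
    rows = []
    for pt in thresholds:
        calls = cohort.scores >= pt
        tp = (calls & (cohort.labels == 1)).sum()
        fp = (calls & (cohort.labels == 0)).sum()
        odds = pt / (1 - pt)
        rows.append({
            "threshold": float(pt),
            "nb_model": float(tp / n - (fp / n) * odds),
            "nb_all": float(prevalence - (1 - prevalence) * odds),
            "nb_none": 0.0,
        })
    return rows


def subgroup_auc(cohort: ScoredCohort, strata) -> dict:
    """Per-stratum AUC with CI and pairwise unpaired DeLong comparisons.

    Single-class strata are excluded with a warning.
    """
    strata = np.asarray(strata)
    per_stratum, excluded = {}, []
    for s in np.unique(strata):
        sel = strata == s
        sub = ScoredCohort(cohort.scores[sel], cohort.labels[sel])
        if len(np.unique(sub.labels)) < 2:
            warnings.warn(f"stratum {s!r} has a single class; excluded")
            excluded.append(s)
            continue
        _, auc, ci = roc_auc(sub)
        per_stratum[s] = {"auc": auc, "ci": ci, "n": int(sel.sum()), "cohort": sub}
    keys = list(per_stratum)
    comparisons = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            comparisons[(a, b)] = unpaired_delong_test(
                per_stratum[a]["cohort"], per_stratum[b]["cohort"]
            )
    for v in per_stratum.values():
        del v["cohort"]
    return {"strata": per_stratum, "comparisons": comparisons, "excluded": excluded}


# ------------------------------------------------------------ packaged counts


def load_reference_confusions() -> dict:
    """Published confusion counts keyed [dataset][model] -> ConfusionMatrix."""
    text = resources.files("cirrdx.data").joinpath("reference_confusions.json").read_text()
    raw = json.loads(text)
    return {
        ds: {model: ConfusionMatrix(**counts) for model, counts in models.items()}
        for ds, models in raw.items()
    }
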