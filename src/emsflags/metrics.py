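"""Evaluation: AUROC with DeLong variance, confusion metrics, filter
variable importance, demographic parity tests, and inter-rater ICC.

AUROC is computed in the Mann-Whitney formulation with ties counted one
half, via midranks. The DeLong variance comes from per-observation
placement values: for positive score ``x_i`` the placement is the fraction
of negatives it outranks (ties half), and symmetrically for negatives; the
AUROC variance is var(V10)/m + var(V01)/n. Wald confidence intervals are
truncated to [0, 1], and perfect separation yields a degenerate zero-width
interval at the point estimate.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import FeatureMatrix

logger = logging.getLogger(__name__)


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(pos, neg):
    """DeLong structural components via midranks."""
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    return v10, v01


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 0.5)."""
    pos, neg = _split_scores(scores, labels)
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


@dataclass
class RocAnalysis:
    """AUROC with DeLong variance and a truncated Wald CI."""

    auc: float
    variance: float
    ci_level: float
    ci: tuple
    n_pos: int
    n_neg: int


def delong_ci(scores, labels, level: float = 0.95) -> RocAnalysis:
    """AUROC with DeLong variance and a ``level`` Wald confidence interval."""
    pos, neg = _split_scores(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("DeLong variance needs at least 2 of each class")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    variance = float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))
    variance = max(variance, 0.0)
    if variance == 0.0:
        ci = (auc, auc)
    else:
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(variance)
        ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    return RocAnalysis(
        auc=auc, variance=variance, ci_level=level, ci=ci,
        n_pos=len(pos), n_neg=len(neg),
    )


@dataclass
class ConfusionTable:
    """Counts at a probability cutoff plus the standard derived metrics.

    Undefined ratios (zero denominators) are reported as ``None``.
    """

    tn: int
    fp: int
    fn: int
    tp: int
    threshold: float
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)
    accuracy: float | None = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num, den):
            return num / den if den else None

        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.ppv = ratio(self.tp, self.tp + self.fp)
        self.npv = ratio(self.tn, self.tn + self.fn)
        self.accuracy = ratio(self.tp + self.tn, self.total)

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def confusion_at_threshold(scores, labels, threshold: float = 0.5) -> ConfusionTable:
    """Tabulate the confusion matrix with prediction positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    truth = labels == 1
    return ConfusionTable(
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tp=int(np.sum(pred & truth)),
        threshold=threshold,
    )


@dataclass
class ImportanceReport:
    """Filter (model-independent) importance: per-predictor AUROC ranking."""

    entries: list  # dicts: column, auc, score, rank

    def top(self, k: int = 5) -> list:
        return [e["column"] for e in self.entries[:k]]


def variable_importance(features: FeatureMatrix, labels) -> ImportanceReport:
    """Score each column by its standalone AUROC as a classifier.

    The direction-agnostic score is max(auc, 1 - auc), so a predictor that
    is informative in reverse still ranks highly; constant columns score
    0.5. Ranks are unique, ties broken by column name.
    """
    labels = np.asarray(labels)
    entries = []
    for j, name in enumerate(features.column_names):
        col = features.values[:, j]
        if np.all(col == col[0]):
            auc = 0.5
        else:
            auc = auroc(col, labels)
        entries.append(
            {"column": name, "auc": auc, "score": max(auc, 1.0 - auc)}
        )
    entries.sort(key=lambda e: (-e["score"], e["column"]))
    for rank, e in enumerate(entries, start=1):
        e["rank"] = rank
    return ImportanceReport(entries=entries)


# ---------------------------------------------------------------------------
# Demographic parity


@dataclass
class ParityReport:
    """Per-group error rates and pairwise equality-of-proportions tests."""

    error_type: str
    rates: dict           # group -> {"errors", "denominator", "rate"}
    pairwise: list        # dicts: groups, statistic, df, p_value[, p_holm]
    excluded: list
    holm: bool


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        correction: bool = True):
    """Chi-square equality-of-proportions test for two groups (df = 1).

    Applies the Yates continuity correction with the standard clamp
    min(0.5, |observed - expected|), so exactly equal proportions give a
    statistic of zero and p = 1.
    """
    if min(n1, n2) <= 0:
        raise ValueError("group denominators must be positive")
    observed = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    if np.any(expected == 0):
        return 0.0, 1.0
    dev = np.abs(observed - expected)
    if correction:
        # all |o - e| are equal in a 2x2 table, so one clamp suffices
        dev = np.maximum(dev - min(0.5, float(dev.max())), 0.0)
    statistic = float(np.sum(dev ** 2 / expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def parity_tests(
    confusions_by_group: dict,
    error_type: str = "false_negative",
    holm: bool = False,
) -> ParityReport:
    """Pairwise equality-of-proportions tests on per-group error rates.

    ``confusions_by_group`` maps group -> (errors, denominator) for one
    fixed error type: false-negative denominators are the true condition
    positives per group, false-positive denominators the true condition
    negatives. Groups with zero denominator are excluded with a warning.
    """
    kept, excluded = {}, []
    for g, (e, d) in confusions_by_group.items():
        if d > 0:
            kept[g] = (int(e), int(d))
        else:
            excluded.append(g)
            logger.warning("parity_tests: group %r excluded (zero denominator)", g)
    if len(kept) < 2:
        raise ValueError("need at least two groups with positive denominators")
    rates = {
        g: {"errors": e, "denominator": d, "rate": e / d}
        for g, (e, d) in kept.items()
    }
    pairwise = []
    for g1, g2 in itertools.combinations(sorted(kept), 2):
        e1, d1 = kept[g1]
        e2, d2 = kept[g2]
        statistic, p = two_proportion_test(e1, d1, e2, d2)
        pairwise.append(
            {"groups": (g1, g2), "statistic": statistic, "df": 1, "p_value": p}
        )
    if holm:
        order = sorted(range(len(pairwise)), key=lambda i: pairwise[i]["p_value"])
        m = len(pairwise)
        running = 0.0
        for rank, i in enumerate(order):
            adj = min((m - rank) * pairwise[i]["p_value"], 1.0)
            running = max(running, adj)
            pairwise[i]["p_holm"] = running
    return ParityReport(
        error_type=error_type, rates=rates, pairwise=pairwise,
        excluded=excluded, holm=holm,
    )


# ---------------------------------------------------------------------------
# Inter-rater reliability


@dataclass
class IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""

    icc_value: float | None
    form: str
    n_subjects: int
    n_raters: int
    note: str = ""
    ci: tuple | None = None


def icc(ratings) -> IccResult:
    """ICC(2,1) from the two-way ANOVA decomposition.

    ``ratings`` is a subjects x raters numeric matrix with no missing
    cells. With no between-subject variance the coefficient is undefined
    and reported as unknown rather than zero.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    form = "two-way random effects, absolute agreement, single rater (ICC(2,1))"
    if np.isclose(denom, 0.0):
        return IccResult(
            icc_value=None, form=form, n_subjects=n, n_raters=k,
            note="undefined: no variance in the ratings (zero denominator)",
        )
    value = float((msr - mse) / denom)
    return IccResult(icc_value=value, form=form, n_subjects=n, n_raters=k)


def roc_points(scores, labels):
    """ROC curve as (fpr, tpr, threshold) arrays for CSV export."""
    from sklearn.metrics import roc_curve

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr
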