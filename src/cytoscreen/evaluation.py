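"""Diagnostic-accuracy machinery for screening evaluation.

Risk-stratum confusion tables, sensitivity/specificity/accuracy/PPV/NPV
with Clopper-Pearson exact 95% CIs, rank-based ROC AUC with a stratified
bootstrap CI, two-sided Pearson chi-square arm comparisons, and the
prevalence-weighting identities that link the printed metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import RiskStratum, SlideGrade, stratum_membership

CI_LEVEL = 0.95
DEFAULT_BOOTSTRAP_REPS = 2000


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screening counts after binarizing by a risk stratum."""

    tp: int
    fp: int
    tn: int
    fn: int
    stratum: Optional[RiskStratum] = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class MetricCI(NamedTuple):
    estimate: float
    lower: float
    upper: float


def clopper_pearson(successes: int, total: int, level: float = CI_LEVEL) -> MetricCI:
    """Exact (Clopper-Pearson) binomial proportion CI."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    a = (1.0 - level) / 2.0
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(a, successes, total - successes + 1))
    upper = (
        1.0 if successes == total else float(stats.beta.ppf(1 - a, successes + 1, total - successes))
    )
    return MetricCI(successes / total, lower, upper)


def confusion_for_stratum(
    predicted: Sequence[Union[str, SlideGrade]],
    truth: Sequence[Union[str, SlideGrade]],
    stratum: RiskStratum,
) -> ConfusionTable:
    """Binarize both call lists by stratum membership and count."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if len(truth) == 0:
        raise ValueError("need at least one case")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        pos_p = stratum_membership(p, stratum)
        pos_t = stratum_membership(t, stratum)
        if pos_t:
            tp += pos_p
            fn += not pos_p
        else:
            fp += pos_p
            tn += not pos_p
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn, stratum=stratum)


@dataclass
class DiagnosticReport:
    """Point estimates with 95% CIs; undefined metrics stay None."""

    n: int
    sensitivity: Optional[MetricCI] = None
    specificity: Optional[MetricCI] = None
    accuracy: Optional[MetricCI] = None
    ppv: Optional[MetricCI] = None
    npv: Optional[MetricCI] = None
    auc: Optional[MetricCI] = None
    stratum: Optional[RiskStratum] = None

    def to_dict(self) -> dict:
        def unpack(m: Optional[MetricCI]):
            return None if m is None else {"estimate": m.estimate, "ci": [m.lower, m.upper]}

        return {
            "n": self.n,
            "stratum": None if self.stratum is None else self.stratum.value,
            "sensitivity": unpack(self.sensitivity),
            "specificity": unpack(self.specificity),
            "accuracy": unpack(self.accuracy),
            "ppv": unpack(self.ppv),
            "npv": unpack(self.npv),
            "auc": unpack(self.auc),
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def diagnostic_metrics(c: ConfusionTable) -> DiagnosticReport:
    """Sensitivity, specificity, accuracy, PPV and NPV with exact CIs.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """

    def ratio_ci(successes: int, total: int) -> Optional[MetricCI]:
        return None if total == 0 else clopper_pearson(successes, total)

    return DiagnosticReport(
        n=c.n,
        stratum=c.stratum,
        sensitivity=ratio_ci(c.tp, c.tp + c.fn),
        specificity=ratio_ci(c.tn, c.tn + c.fp),
        accuracy=ratio_ci(c.tp + c.tn, c.n),
        ppv=ratio_ci(c.tp, c.tp + c.fp),
        npv=ratio_ci(c.tn, c.tn + c.fn),
    )


class PrevalenceWeighted(NamedTuple):
    accuracy: float
    npv: float
    ppv: float


def prevalence_weighted_metrics(
    sensitivity: float, specificity: float, prevalence: float
) -> PrevalenceWeighted:
    """Accuracy/NPV/PPV implied by sensitivity, specificity and prevalence.

    accuracy = prev*sens + (1-prev)*spec;
    npv = (1-prev)*spec / ((1-prev)*spec + prev*(1-sens));
    ppv = prev*sens / (prev*sens + (1-prev)*(1-spec)).
    Degenerate denominators yield NaN.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    acc = prevalence * sensitivity + (1.0 - prevalence) * specificity
    npv_den = (1.0 - prevalence) * specificity + prevalence * (1.0 - sensitivity)
    ppv_den = prevalence * sensitivity + (1.0 - prevalence) * (1.0 - specificity)
    npv = (1.0 - prevalence) * specificity / npv_den if npv_den > 0 else math.nan
    ppv = prevalence * sensitivity / ppv_den if ppv_den > 0 else math.nan
    return PrevalenceWeighted(accuracy=acc, npv=npv, ppv=ppv)


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie correction."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    rank_sum = float(ranks[labels].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    compute_ci: bool = True,
) -> MetricCI:
    """ROC AUC via the rank formulation; CI by stratified bootstrap.

    Positives and negatives are resampled separately in each of
    ``n_boot`` replicates; the CI is the percentile interval. Requires
    both label values to be present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if labels.all() or not labels.any():
        raise ValueError("roc_auc requires both positive and negative labels")
    auc = _auc_rank(scores, labels)
    if not compute_ci:
        return MetricCI(auc, math.nan, math.nan)
    rng = np.random.default_rng(seed)
    pos, neg = scores[labels], scores[~labels]
    reps = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([bp, bn])
        lbl = np.zeros(len(s), dtype=bool)
        lbl[: len(bp)] = True
        reps[i] = _auc_rank(s, lbl)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return MetricCI(auc, float(lo), float(hi))


def roc_curve_points(
    scores: Sequence[float], labels: Sequence[bool]
) -> pd.DataFrame:
    """ROC coordinates (threshold, fpr, tpr) for CSV export/plotting."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    thresholds, fprs, tprs = [np.inf], [0.0], [0.0]
    tp = fp = 0
    for i in range(len(scores)):
        tp += bool(labels[i])
        fp += not labels[i]
        if i + 1 < len(scores) and scores[i + 1] == scores[i]:
            continue
        thresholds.append(float(scores[i]))
        tprs.append(tp / n_pos if n_pos else 0.0)
        fprs.append(fp / n_neg if n_neg else 0.0)
    return pd.DataFrame({"threshold": thresholds, "fpr": fprs, "tpr": tprs})


def compare_proportions_chi2(
    a_success: int, a_total: int, b_success: int, b_total: int
) -> Tuple[float, float]:
    """Two-sided Pearson chi-square (no continuity correction) on a 2x2 table."""
    if a_total <= 0 or b_total <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= a_success <= a_total and 0 <= b_success <= b_total):
        raise ValueError("successes must lie within their totals")
    table = np.array(
        [[a_success, a_total - a_success], [b_success, b_total - b_success]],
        dtype=np.float64,
    )
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("chi-square is undefined with an empty margin")
    if a_success / a_total == b_success / b_total:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def sensitivity_difference(
    assisted: Union[DiagnosticReport, float], unassisted: Union[DiagnosticReport, float]
) -> float:
    """(assisted - unassisted) sensitivity in percentage points, 1 dp."""

    def sens(x) -> float:
        if isinstance(x, DiagnosticReport):
            if x.sensitivity is None:
                raise ValueError("report has undefined sensitivity")
            return x.sensitivity.estimate
        return float(x)

    return round((sens(assisted) - sens(unassisted)) * 100.0, 1)


def evaluate_predictions(
    predicted: Sequence[Union[str, SlideGrade]],
    truth: Sequence[Union[str, SlideGrade]],
    scores: Optional[Sequence[float]] = None,
    strata: Sequence[RiskStratum] = tuple(RiskStratum),
    seed: int = 0,
) -> Dict[RiskStratum, DiagnosticReport]:
    """Full per-stratum report set; AUC uses ``scores`` when provided.

    ``scores`` should be per-slide stratum-positivity scores keyed the
    same for every stratum (e.g. the abnormality score) or omitted.
    """
    reports: Dict[RiskStratum, DiagnosticReport] = {}
    for stratum in strata:
        table = confusion_for_stratum(predicted, truth, stratum)
        report = diagnostic_metrics(table)
        if scores is not None:
            y = [stratum_membership(t, stratum) for t in truth]
            if any(y) and not all(y):
                report.auc = roc_auc(scores, y, seed=seed)
        reports[stratum] = report
    return reports
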