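"""Classification metrics with binomial confidence intervals and flow accounting.

Metrics follow the standard confusion-matrix definitions.  Confidence
intervals use the normal (binomial) approximation p ± z·sqrt(p(1−p)/n),
clipped to [0, 1]; n is the metric's own denominator (e.g. the positives for
sensitivity), which is a documented convention rather than a replication of
any published interval.  Undefined metrics (zero denominator) are flagged as
None, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "classification_metrics",
    "auc",
    "binomial_ci",
    "near_miss_precision",
    "prevalence",
    "flow_accounting",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(bool)
        yp = np.asarray(y_pred).astype(bool)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum(yt & yp)),
            fp=int(np.sum(~yt & yp)),
            tn=int(np.sum(~yt & ~yp)),
            fn=int(np.sum(yt & ~yp)),
        )


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def classification_metrics(cm: ConfusionMatrix) -> Dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, precision, balanced accuracy, F1, MCC.

    Returns None for any metric whose denominator is zero.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    acc = _safe_div(tp + tn, cm.total)
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2.0 * prec * sens / (prec + sens)
    else:
        f1 = None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "balanced_accuracy": bal,
        "f1": f1,
        "mcc": mcc,
    }


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) AUC; ties between classes count 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(s)  # average ranks handle ties as 0.5
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def binomial_ci(p_hat: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Normal-approximation binomial CI, clipped to [0, 1]."""
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


def near_miss_precision(predicted_positive: Sequence[bool], reference_zone: Sequence[str]) -> Optional[float]:
    """Fraction of predicted very-high cases whose reference lies in the high-fragility zone.

    ``reference_zone`` carries the reference BFI category per case
    ({none, high, very_high}); the zone {high, very_high} contains every true
    positive, so this is never below the plain precision.
    """
    pred = np.asarray(predicted_positive).astype(bool)
    zones = np.asarray(reference_zone)
    n_pred = int(pred.sum())
    if n_pred == 0:
        return None
    in_zone = np.isin(zones[pred], ("high", "very_high"))
    return float(in_zone.sum() / n_pred)


def prevalence(n_pos: int, n_total: int) -> float:
    """Prevalence as a percentage with half-up rounding to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_pos <= n_total):
        raise ValueError("n_pos must be in [0, n_total]")
    pct = Decimal(100 * n_pos) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def flow_accounting(stages: Sequence[Tuple[str, int]]) -> List[Dict[str, int]]:
    """Attrition table from (stage name, n excluded at stage) given an initial count.

    ``stages`` is [(stage0_name, n_in)] + [(name, n_excluded), ...]; returns
    records with stage_in − excluded = stage_out enforced at every stage.
    """
    if not stages:
        raise ValueError("at least the initial stage is required")
    name0, n_in = stages[0]
    table = [{"stage": name0, "n_in": int(n_in), "n_excluded": 0, "n_out": int(n_in)}]
    current = int(n_in)
    for name, excluded in stages[1:]:
        excluded = int(excluded)
        if excluded < 0 or excluded > current:
            raise ValueError(f"stage {name}: excluded count {excluded} out of range")
        out = current - excluded
        table.append({"stage": name, "n_in": current, "n_excluded": excluded, "n_out": out})
        current = out
    return table


def flow_from_eligibility(reasons_per_record: Sequence[Sequence[str]]) -> Dict[str, int]:
    """Per-reason exclusion counts plus the distinct excluded-record count.

    A record with several violation codes contributes once to ``n_excluded``
    but once per code to the reason tally, so the per-reason sum can exceed
    the record count.
    """
    counts: Dict[str, int] = {}
    excluded = 0
    for reasons in reasons_per_record:
        if reasons:
            excluded += 1
        for code in reasons:
            counts[code] = counts.get(code, 0) + 1
    counts["n_records"] = len(reasons_per_record)
    counts["n_excluded"] = excluded
    return counts


def metrics_report(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Optional[Sequence[float]] = None,
    strata: Optional[Sequence[str]] = None,
    level: float = 0.95,
) -> List[Dict]:
    """Stratified metric records with binomial CIs.

    One record per stratum plus an ``overall`` record.  CI n is each metric's
    own denominator; AUC (computed when scores are given and both classes are
    present) is reported without a CI.
    """
    yt = np.asarray(y_true).astype(bool)
    yp = np.asarray(y_pred).astype(bool)
    sc = None if scores is None else np.asarray(scores, dtype=float)
    st = np.asarray(strata) if strata is not None else None

    def one(mask: np.ndarray, key: str) -> Dict:
        cm = ConfusionMatrix.from_predictions(yt[mask], yp[mask])
        m = classification_metrics(cm)
        denoms = {
            "accuracy": cm.total,
            "sensitivity": cm.tp + cm.fn,
            "specificity": cm.tn + cm.fp,
            "precision": cm.tp + cm.fp,
            "balanced_accuracy": cm.total,
            "f1": cm.total,
            "mcc": cm.total,
        }
        rec: Dict = {
            "stratum": key,
            "n": cm.total,
            "prevalence_pct": prevalence(cm.tp + cm.fn, cm.total),
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        }
        for name, value in m.items():
            if value is None:
                rec[name] = None
                rec[name + "_ci"] = None
            else:
                # MCC lives in [-1,1]; CI convention applies to proportions only
                if name == "mcc":
                    rec[name] = value
                    rec[name + "_ci"] = None
                    continue
                lo, hi = binomial_ci(min(max(value, 0.0), 1.0), denoms[name], level)
                rec[name] = value
                rec[name + "_ci"] = (lo, hi)
        if sc is not None and 0 < yt[mask].sum() < mask.sum():
            rec["auc"] = auc(sc[mask], yt[mask])
        else:
            rec["auc"] = None
        return rec

    records = [one(np.ones(len(yt), dtype=bool), "overall")]
    if st is not None:
        for key in sorted(set(st.tolist())):
            records.append(one(st == key, str(key)))
    return records
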