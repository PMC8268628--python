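"""Performance evaluation: confusion metrics, ROC/AUC, the DeLong test for
correlated AUCs, AFP cut-off comparators, clinical-subgroup reports, and
cumulative sensitivity by tumor size."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

from .afp import parse_afp

__all__ = [
    "ConfusionMetrics",
    "ROCResult",
    "SubgroupReport",
    "confusion_metrics",
    "roc_points",
    "delong_compare",
    "afp_cutoff_classifier",
    "subgroup_report",
    "cumulative_sensitivity_by_size",
    "round_half_up",
    "scores_for_roc",
    "LESION_SIZE_BINS",
]

LESION_SIZE_BINS: Tuple[Tuple[str, float, float], ...] = (
    ("<3", 0.0, 3.0),
    ("[3,5)", 3.0, 5.0),
    ("[5,7)", 5.0, 7.0),
    ("[7,10)", 7.0, 10.0),
    ("[10,15)", 10.0, 15.0),
    (">=15", 15.0, math.inf),
)


def round_half_up(x: float) -> int:
    """Integer percentage rounding with .5 going up (table convention)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMetrics:
    correct_hcc: int
    total_hcc: int
    correct_no_hcc: int
    total_no_hcc: int

    @property
    def sensitivity(self) -> Optional[float]:
        return self.correct_hcc / self.total_hcc if self.total_hcc else None

    @property
    def specificity(self) -> Optional[float]:
        return self.correct_no_hcc / self.total_no_hcc if self.total_no_hcc else None

    @property
    def accuracy(self) -> Optional[float]:
        total = self.total_hcc + self.total_no_hcc
        return (self.correct_hcc + self.correct_no_hcc) / total if total else None

    @property
    def sensitivity_pct(self) -> Optional[int]:
        s = self.sensitivity
        return None if s is None else round_half_up(100 * s)

    @property
    def specificity_pct(self) -> Optional[int]:
        s = self.specificity
        return None if s is None else round_half_up(100 * s)

    @property
    def accuracy_pct(self) -> Optional[int]:
        a = self.accuracy
        return None if a is None else round_half_up(100 * a)


def confusion_metrics(truth: Sequence[bool], calls: Sequence) -> ConfusionMetrics:
    """Sensitivity/specificity/accuracy with correct/total counts.

    ``calls`` may be booleans or the labels "Cancer"/"NoCancer"; QCFail calls
    must be excluded upstream (they are rejected here).
    """
    y = np.asarray(truth, dtype=bool)
    c = np.asarray(calls)
    if c.dtype.kind in "UO":
        if np.any(c == "QCFail"):
            raise ValueError("QCFail calls must be excluded (with a reported count)")
        pred = c == "Cancer"
    else:
        pred = c.astype(bool)
    if len(y) != len(pred):
        raise ValueError("truth and calls must be the same length")
    return ConfusionMetrics(
        correct_hcc=int((pred & y).sum()),
        total_hcc=int(y.sum()),
        correct_no_hcc=int((~pred & ~y).sum()),
        total_no_hcc=int((~y).sum()),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float


def scores_for_roc(classifications: Sequence) -> np.ndarray:
    """Effective scores for the hierarchical test's ROC family.

    Samples classified by the pre-classifier-Poor or high-AFP rules are
    "Cancer" at every classifier cutoff, so their effective score is 1.0;
    machine-learning-routed samples use their ensemble score.
    """
    out = []
    for c in classifications:
        if c.route in ("PRECLASSIFIER_POOR", "HIGH_AFP"):
            out.append(1.0)
        elif c.route == "ML_SCORE":
            out.append(float(c.score))
        else:
            raise ValueError("QCFail classifications cannot enter the ROC")
    return np.asarray(out)


def roc_points(scores: Sequence[float], truth: Sequence[bool]) -> ROCResult:
    """ROC curve (one point per distinct score plus the endpoints) and
    trapezoidal AUC."""
    y = np.asarray(truth, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes")
    fpr, tpr, thresh = roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresh, sensitivity=tpr,
                     one_minus_specificity=fpr, auc=auc)


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs
# ---------------------------------------------------------------------------

def _midrank_placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Structural components of the AUC via midranks (ties count 1/2)."""
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    r_all = rankdata(all_s)          # midranks in the pooled sample
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v_pos = (r_all[:m] - r_pos) / n             # V10_i
    v_neg = 1.0 - (r_all[m:] - r_neg) / m       # V01_j
    auc = float(v_pos.mean())
    return v_pos, v_neg, auc


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    truth: Sequence[bool],
) -> Tuple[float, float, float, float]:
    """DeLong test for two correlated (paired-sample) ROC AUCs.

    Returns (auc_a, auc_b, variance of the AUC difference, two-sided p from
    the normal approximation).
    """
    y = np.asarray(truth, dtype=bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(y) or len(b) != len(y):
        raise ValueError("paired design: both score vectors must cover the same samples")
    m, n = int(y.sum()), int((~y).sum())
    if m < 2 or n < 2:
        raise ValueError("DeLong requires at least 2 samples per class")

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((a, b)):
        v10[i], v01[i], aucs[i] = _midrank_placements(s[y], s[~y])
    s10 = np.cov(v10)      # 2x2 covariance of positive-side components
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2 * norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), var_diff, min(p, 1.0)


# ---------------------------------------------------------------------------
# AFP comparator
# ---------------------------------------------------------------------------

def afp_cutoff_classifier(afp_values: Sequence, cutoff: float = 20.0) -> np.ndarray:
    """Cancer iff AFP >= cutoff; censored ">=10,000" is Cancer, "<bound" is not."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return np.array([parse_afp(v).geq(cutoff) for v in afp_values], dtype=bool)


# ---------------------------------------------------------------------------
# subgroup reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupReport:
    grouping: str
    table: pd.DataFrame  # rows = groups; columns = correct/total/percent per arm

    def arm_totals(self, arm: str) -> Tuple[int, int]:
        return int(self.table[f"{arm}_correct"].sum()), int(self.table[f"{arm}_total"].sum())


def _lesion_bin(size: Optional[float]) -> str:
    if size is None or (isinstance(size, float) and math.isnan(size)):
        return "NA"
    for name, lo, hi in LESION_SIZE_BINS:
        if lo <= size < hi:
            return name
    return "NA"


def subgroup_report(
    correct: Mapping[str, bool],
    records: pd.DataFrame,
    grouping: str,
) -> SubgroupReport:
    """Correct/total counts and integer percentages per clinical subgroup.

    ``correct`` maps sample_id -> whether the test call matched the truth;
    ``records`` carries the clinical covariates ('hcc' plus the grouping
    variable; lesion sizes are binned as <3, [3,5), [5,7), [7,10), [10,15),
    >=15 cm, NA).  Missing values form an explicit "NA" group so counts
    always sum to the arm totals.
    """
    if grouping not in records.columns and grouping != "lesion_size_bin":
        raise ValueError(f"unknown grouping variable {grouping!r}")
    rows: Dict[str, Dict[str, int]] = {}
    for sid, rec in records.iterrows():
        sid = str(sid)
        if sid not in correct:
            continue
        if grouping == "lesion_size_bin":
            g = _lesion_bin(rec.get("lesion_size_cm"))
        else:
            val = rec.get(grouping)
            g = "NA" if val is None or (isinstance(val, float) and math.isnan(val)) else str(val)
        arm = "hcc" if bool(rec["hcc"]) else "no_hcc"
        r = rows.setdefault(g, {"hcc_correct": 0, "hcc_total": 0,
                                "no_hcc_correct": 0, "no_hcc_total": 0})
        r[f"{arm}_total"] += 1
        r[f"{arm}_correct"] += int(correct[sid])
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    for arm in ("hcc", "no_hcc"):
        table[f"{arm}_pct"] = [
            round_half_up(100 * c / t) if t else None
            for c, t in zip(table[f"{arm}_correct"], table[f"{arm}_total"])
        ]
    return SubgroupReport(grouping, table)


def cumulative_sensitivity_by_size(
    correct: Sequence[bool],
    lesion_sizes: Sequence[Optional[float]],
) -> pd.DataFrame:
    """Sensitivity among tumors up to each observed size threshold.

    Returns a frame with one row per distinct size: (size_threshold,
    sensitivity, n).  NA sizes are excluded from the curve; their count is
    stored in ``frame.attrs["n_missing_size"]``.
    """
    pairs = [
        (float(s), bool(c))
        for c, s in zip(correct, lesion_sizes)
        if s is not None and not (isinstance(s, float) and math.isnan(s))
    ]
    n_missing = len(list(correct)) - len(pairs)
    if not pairs:
        raise ValueError("no sized tumors")
    pairs.sort()
    sizes = np.array([p[0] for p in pairs])
    hits = np.cumsum([p[1] for p in pairs])
    counts = np.arange(1, len(pairs) + 1)
    distinct = np.unique(sizes)
    idx = np.searchsorted(sizes, distinct, side="right") - 1
    frame = pd.DataFrame({
        "size_threshold_cm": distinct,
        "sensitivity": hits[idx] / counts[idx],
        "n": counts[idx],
    })
    frame.attrs["n_missing_size"] = n_missing
    return frame
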