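"""Performance measures for the two-class (lyase vs nonlyase) problem.

Sensitivity (Sn), specificity (Sp), overall accuracy (OA), average
accuracy (AA = (Sn+Sp)/2, i.e. balanced accuracy) and Matthews correlation
coefficient (MCC) are computed from integer confusion counts. Rates are
stored as exact ratios in percent; rounding to 2 dp (rates) and 3 dp (MCC)
happens only at display time. AA and the ROC curve are the primary
measures because the benchmark is imbalanced (few positives).

``counts_from_rates`` inverts the rate definitions: given printed Sn/Sp
percentages and the class sizes it recovers the unique integer confusion
counts, which lets published summary rows be checked for internal
arithmetic consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import sklearn.metrics as _skm

from .errors import InconsistencyError, UndefinedROCError


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts; positives = lyases."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    """Rates in percent, MCC in [−1, 1], optional auROC in [0, 1]."""

    sn: float
    sp: float
    oa: float
    aa: float
    mcc: float
    auroc: float | None = None
    counts: ConfusionCounts | None = None
    mcc_degenerate: bool = field(default=False, compare=False)

    def to_dict(self) -> dict:
        d = {
            "Sn": self.sn,
            "Sp": self.sp,
            "MCC": self.mcc,
            "OA": self.oa,
            "AA": self.aa,
        }
        if self.auroc is not None:
            d["auROC"] = self.auroc
        if self.counts is not None:
            d.update(
                TP=self.counts.tp, FN=self.counts.fn, TN=self.counts.tn, FP=self.counts.fp
            )
        return d

    def format_row(self) -> str:
        """Display at the conventional precision: rates 2 dp, MCC 3 dp."""
        parts = [
            f"Sn={self.sn:.2f}%",
            f"Sp={self.sp:.2f}%",
            f"MCC={self.mcc:.3f}",
            f"OA={self.oa:.2f}%",
            f"AA={self.aa:.2f}%",
        ]
        if self.auroc is not None:
            parts.append(f"auROC={self.auroc:.3f}")
        return "  ".join(parts)


def compute_metrics(counts: ConfusionCounts, auroc: float | None = None) -> MetricsReport:
    """Sn, Sp, MCC, OA and AA from confusion counts.

    Requires at least one sample in each class. If any factor of the MCC
    denominator is zero the MCC is reported as 0 with ``mcc_degenerate``
    set (a common convention; the statistic is undefined there).
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if counts.n_pos < 1 or counts.n_neg < 1:
        raise ValueError("both classes must be nonempty")
    sn = 100.0 * tp / counts.n_pos
    sp = 100.0 * tn / counts.n_neg
    oa = 100.0 * (tp + tn) / (counts.n_pos + counts.n_neg)
    aa = (sn + sp) / 2.0
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        sn=sn, sp=sp, oa=oa, aa=aa, mcc=mcc, auroc=auroc, counts=counts,
        mcc_degenerate=degenerate,
    )


def metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, auroc: float | None = None
) -> MetricsReport:
    """Convenience: confusion counts from 0/1 arrays, then the report."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )
    return compute_metrics(counts, auroc=auroc)


def counts_from_rates(
    sn_percent: float, sp_percent: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Recover integer confusion counts from printed Sn/Sp percentages.

    Searches the integer TP (resp. TN) whose exact rate rounds to the
    printed 2-dp percentage; when several qualify the closest is taken.

    Raises
    ------
    InconsistencyError
        If no integer count reproduces a printed rate at 2 dp.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    for rate in (sn_percent, sp_percent):
        if not 0.0 <= rate <= 100.0:
            raise ValueError(f"rate {rate} outside [0, 100]")

    def _recover(rate: float, n: int, what: str) -> int:
        # half-unit-in-last-place tolerance on a 2-dp percentage
        cands = [k for k in range(n + 1) if abs(100.0 * k / n - rate) <= 0.005 + 1e-9]
        if not cands:
            raise InconsistencyError(
                f"no integer {what} count out of {n} yields {rate:.2f}%"
            )
        return min(cands, key=lambda k: abs(100.0 * k / n - rate))

    tp = _recover(sn_percent, n_pos, "true-positive")
    tn = _recover(sp_percent, n_neg, "true-negative")
    return ConfusionCounts(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


@dataclass(frozen=True)
class RocCurve:
    """ROC points (1−Sp on x, Sn on y) and the area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"one_minus_Sp": self.fpr, "Sn": self.tpr, "threshold": self.thresholds}
        )


def roc_curve(decision_values: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over all distinct thresholds plus the tie-aware auROC.

    The area equals the Mann–Whitney statistic with ties credited 1/2,
    which coincides with trapezoidal integration of the curve.
    """
    labels = np.asarray(labels, dtype=int)
    decision_values = np.asarray(decision_values, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise UndefinedROCError("ROC requires both classes to be present")
    fpr, tpr, thr = _skm.roc_curve(labels, decision_values)
    auroc = float(_skm.roc_auc_score(labels, decision_values))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auroc=auroc)
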