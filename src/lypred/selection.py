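"""ANOVA F-score feature ranking and incremental feature selection (IFS).

For each feature the two-group one-way ANOVA statistic

    F = SSB / (SSW / (N - 2))

is computed, where SSB is the between-class and SSW the within-class sum
of squares (numerator df 1 for two classes, denominator df N − 2). Larger
F means better univariate class separation. IFS then evaluates nested
prefixes of the F-descending ranking with a cross-validated classifier and
keeps the prefix with the best criterion; ties go to the smaller subset,
since fewer features means less overfitting risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .features import FeatureMatrix
from .metrics import MetricsReport

logger = logging.getLogger(__name__)

#: Evaluator contract: (feature sub-matrix, labels) -> MetricsReport.
Evaluator = Callable[[pd.DataFrame, np.ndarray], MetricsReport]


@dataclass
class FScoreRanking:
    """Per-feature F values and the F-descending permutation."""

    scores: np.ndarray
    order: np.ndarray
    names: list[str] = field(repr=False)

    @property
    def ranked_names(self) -> list[str]:
        return [self.names[i] for i in self.order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.ranked_names,
                "F": self.scores[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def anova_f_scores(matrix: FeatureMatrix) -> FScoreRanking:
    """Rank every feature by its two-group ANOVA F-score.

    Degenerate features (zero pooled within-class variance) cannot produce
    a finite ratio: when the class means are also equal F is set to 0 and
    the feature ranks last; when the means differ the feature separates the
    classes perfectly, so it receives the largest finite score plus one and
    a warning is logged.

    Ties are broken by original column index (stable sort) for
    reproducibility.
    """
    y = matrix.y
    X = matrix.X.to_numpy(dtype=float)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientDataError(
            f"each class needs >= 2 samples (got {len(pos)} positive, {len(neg)} negative)"
        )
    n1, n0 = len(pos), len(neg)
    mu1, mu0 = pos.mean(axis=0), neg.mean(axis=0)
    mu = X.mean(axis=0)
    ssb = n1 * (mu1 - mu) ** 2 + n0 * (mu0 - mu) ** 2
    ssw = ((pos - mu1) ** 2).sum(axis=0) + ((neg - mu0) ** 2).sum(axis=0)
    dfw = n1 + n0 - 2

    scores = np.zeros_like(ssb)
    ok = ssw > 0.0
    scores[ok] = ssb[ok] / (ssw[ok] / dfw)
    separating = (~ok) & (ssb > 0.0)
    if separating.any():
        finite_max = scores[ok].max() if ok.any() else 0.0
        scores[separating] = finite_max + 1.0
        logger.warning(
            "%d feature(s) separate the classes with zero within-class "
            "variance; assigned top rank", int(separating.sum()),
        )
    order = np.argsort(-scores, kind="stable")
    return FScoreRanking(scores=scores, order=order, names=list(matrix.X.columns))


@dataclass
class IFSResult:
    """Outcome of incremental feature selection."""

    subset_sizes: list[int]
    reports: list[MetricsReport]
    best_size: int
    best_features: list[str]
    best_report: MetricsReport
    criterion: str

    def curve_frame(self) -> pd.DataFrame:
        rows = []
        for size, rep in zip(self.subset_sizes, self.reports):
            rows.append(
                {
                    "size": size,
                    "Sn": rep.sn,
                    "Sp": rep.sp,
                    "MCC": rep.mcc,
                    "OA": rep.oa,
                    "AA": rep.aa,
                }
            )
        return pd.DataFrame(rows)


def incremental_feature_selection(
    matrix: FeatureMatrix,
    ranking: FScoreRanking,
    evaluator: Evaluator,
    criterion: str = "OA",
    max_size: int | None = None,
    stride: int = 1,
) -> IFSResult:
    """Evaluate nested prefixes of the ranking; keep the best one.

    Subsets of sizes 1, 1+stride, ... up to ``max_size`` (default: all
    features) are scored by the evaluator; the chosen subset is the
    smallest size attaining the maximum of the criterion (``"OA"`` or
    ``"AA"``).
    """
    crit = criterion.lower()
    if crit not in ("oa", "aa"):
        raise ValueError(f"criterion must be 'OA' or 'AA', got {criterion!r}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    p = matrix.n_features
    limit = p if max_size is None else min(max_size, p)
    sizes = list(range(1, limit + 1, stride))

    reports: list[MetricsReport] = []
    for size in sizes:
        cols = ranking.order[:size]
        sub = matrix.X.iloc[:, cols]
        try:
            rep = evaluator(sub, matrix.y)
        except Exception as exc:
            raise type(exc)(f"IFS evaluation failed at subset size {size}: {exc}") from exc
        reports.append(rep)
        logger.debug("IFS size=%d %s", size, rep.format_row())

    values = [getattr(rep, crit) for rep in reports]
    best_idx = int(np.argmax(values))  # argmax keeps the first (smallest) maximizer
    best_size = sizes[best_idx]
    return IFSResult(
        subset_sizes=sizes,
        reports=reports,
        best_size=best_size,
        best_features=ranking.ranked_names[:best_size],
        best_report=reports[best_idx],
        criterion=criterion.upper(),
    )
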