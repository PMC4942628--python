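"""SVM training, cross-validation, (g, δ) grid search and threshold tuning.

The predictor is an RBF-kernel support vector machine on min-max scaled
([−1, 1]) PseAAC features. Parameter search follows the published
protocol: for every (g, δ) cell of the grid the features are ranked by
ANOVA F-score and incremental feature selection is run with stratified
5-fold cross-validation; the winning cell maximizes the cross-validated
overall accuracy, ties going to the smallest feature subset. The chosen
subset is then verified with jackknife (leave-one-out) cross-validation,
and — because the benchmark is imbalanced — a decision-value threshold is
swept to maximize the average accuracy instead of reweighting classes.

Scaling is always fit on the training fold only, so no information about
a held-out sample leaks into its decision value.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from . import __version__
from .errors import ConfigError, SequenceTooShortError, StratificationError
from .features import (
    FeatureMatrix,
    PseAACParams,
    encode_matrix,
    feature_names,
)
from .metrics import MetricsReport, metrics_from_predictions, roc_curve
from .physchem import PhysChemTable, default_table
from .seqio import ProteinRecord, validate_sequence
from .selection import Evaluator, IFSResult, anova_f_scores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol.

    ``jackknife=True`` selects leave-one-out; otherwise stratified k-fold
    (default 5 folds) with label-stratified, seed-shuffled assignment.
    """

    n_folds: int = 5
    stratified: bool = True
    seed: int = 0
    jackknife: bool = False


@dataclass(frozen=True)
class SVMParams:
    """LIBSVM-style hyperparameters (scikit-learn SVC backend)."""

    C: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"


def _make_pipeline(svm: SVMParams) -> Pipeline:
    return Pipeline(
        [
            ("scale", MinMaxScaler(feature_range=(-1.0, 1.0))),
            ("svm", SVC(kernel=svm.kernel, C=svm.C, gamma=svm.gamma)),
        ]
    )


def _splitter(cv: CVConfig, n: int, y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present")
    if cv.jackknife:
        if counts.min() < 2:
            raise StratificationError(
                "jackknife needs >= 2 samples per class so every training "
                "fold keeps both classes"
            )
        return LeaveOneOut()
    if cv.n_folds < 2:
        raise ConfigError("n_folds must be >= 2")
    if cv.n_folds >= n:
        raise ConfigError(
            f"n_folds={cv.n_folds} with n={n} samples: set jackknife=True "
            "for leave-one-out"
        )
    if cv.stratified:
        if counts.min() < cv.n_folds:
            raise StratificationError(
                f"smallest class has {counts.min()} samples < {cv.n_folds} folds"
            )
        return StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    raise ConfigError("non-stratified k-fold is not supported; use stratified or jackknife")


def _oof_decision_values(
    X: pd.DataFrame | np.ndarray, y: np.ndarray, cv: CVConfig, svm: SVMParams
) -> np.ndarray:
    """One out-of-fold decision value per sample; scaling fit per training fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    splitter = _splitter(cv, len(y), y)
    return cross_val_predict(
        _make_pipeline(svm), X, y, cv=splitter, method="decision_function"
    )


def cross_validated_scores(
    matrix: FeatureMatrix, cv: CVConfig, svm: SVMParams | None = None
) -> np.ndarray:
    """Out-of-fold SVM decision values for every sample of the matrix."""
    return _oof_decision_values(matrix.X, matrix.y, cv, svm or SVMParams())


def make_cv_evaluator(cv: CVConfig, svm: SVMParams | None = None) -> Evaluator:
    """Build the IFS evaluator: CV decision values, labels at threshold 0."""
    svm = svm or SVMParams()

    def evaluate(X: pd.DataFrame, y: np.ndarray) -> MetricsReport:
        dv = _oof_decision_values(X, y, cv, svm)
        auroc = roc_curve(dv, y).auroc
        return metrics_from_predictions(y, (dv >= 0.0).astype(int), auroc=auroc)

    return evaluate


def cv_incremental_feature_selection(
    matrix: FeatureMatrix,
    cv: CVConfig,
    svm: SVMParams | None = None,
    criterion: str = "OA",
    max_size: int | None = None,
    stride: int = 1,
) -> IFSResult:
    """Incremental feature selection with fold-internal ranking.

    For each CV fold the ANOVA ranking is recomputed on the training
    samples only, and every prefix size is evaluated on the held-out
    fold. This keeps the held-out samples out of the feature-selection
    step, so on signal-free data the curve stays at chance level instead
    of inheriting the optimistic bias of ranking on all samples.
    ``best_features`` is the winning-size prefix of the full-data ranking
    (the subset a final model would use).
    """
    crit = criterion.lower()
    if crit not in ("oa", "aa"):
        raise ValueError(f"criterion must be 'OA' or 'AA', got {criterion!r}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    svm = svm or SVMParams()
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y
    limit = matrix.n_features if max_size is None else min(max_size, matrix.n_features)
    sizes = list(range(1, limit + 1, stride))
    splitter = _splitter(cv, len(y), y)

    dv = np.zeros((len(sizes), len(y)))
    for train_idx, test_idx in splitter.split(X, y):
        fold = FeatureMatrix(X=matrix.X.iloc[train_idx], y=y[train_idx])
        fold_order = anova_f_scores(fold).order
        for si, k in enumerate(sizes):
            cols = fold_order[:k]
            pipe = _make_pipeline(svm)
            pipe.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            dv[si, test_idx] = pipe.decision_function(X[np.ix_(test_idx, cols)])

    reports = [
        metrics_from_predictions(
            y, (dv[si] >= 0.0).astype(int), auroc=roc_curve(dv[si], y).auroc
        )
        for si in range(len(sizes))
    ]
    values = [getattr(rep, crit) for rep in reports]
    best_idx = int(np.argmax(values))  # first maximizer = smallest size
    best_size = sizes[best_idx]
    full_ranking = anova_f_scores(matrix)
    return IFSResult(
        subset_sizes=sizes,
        reports=reports,
        best_size=best_size,
        best_features=full_ranking.ranked_names[:best_size],
        best_report=reports[best_idx],
        criterion=criterion.upper(),
    )


@dataclass
class ThresholdResult:
    threshold: float
    report: MetricsReport


def tune_threshold(
    decision_values: np.ndarray,
    labels: np.ndarray,
    criterion: str = "AA",
) -> ThresholdResult:
    """Sweep decision-value cutoffs; keep the one maximizing the criterion.

    Candidates are the midpoints between consecutive sorted distinct
    decision values plus sentinels below and above the range, so every
    achievable confusion table is visited. A sample is called positive
    when its decision value is >= the threshold. Ties on the criterion are
    broken by higher MCC, then higher OA, then the smaller threshold.
    """
    crit = criterion.lower()
    if crit not in ("aa", "oa", "mcc"):
        raise ValueError(f"criterion must be AA, OA or MCC, got {criterion!r}")
    dv = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(dv)
    if len(uniq) == 1:
        warnings.warn("all decision values identical; threshold is degenerate")
        candidates = np.array([uniq[0]])
    else:
        mid = (uniq[:-1] + uniq[1:]) / 2.0
        candidates = np.concatenate([[uniq[0] - 1.0], mid, [uniq[-1] + 1.0]])

    auroc = roc_curve(dv, y).auroc if len(uniq) > 1 else None
    best: tuple | None = None
    best_result: ThresholdResult | None = None
    for thr in candidates:
        rep = metrics_from_predictions(y, (dv >= thr).astype(int), auroc=auroc)
        key = (getattr(rep, crit), rep.mcc, rep.oa, -thr)
        if best is None or key > best:
            best = key
            best_result = ThresholdResult(threshold=float(thr), report=rep)
    assert best_result is not None
    return best_result


def tune_svm_hyperparams(
    matrix: FeatureMatrix,
    cv: CVConfig,
    C_grid: Sequence[float] = tuple(2.0**k for k in range(-5, 16, 2)),
    gamma_grid: Sequence[float] = tuple(2.0**k for k in range(-15, 4, 2)),
) -> tuple[SVMParams, float]:
    """Coarse (C, γ) grid search by cross-validated overall accuracy.

    Intended for the final, already-selected feature subset; IFS and the
    (g, δ) grid use fixed defaults for tractability (see docs). Returns
    the winning parameters and their CV overall accuracy.
    """
    best: tuple[float, float, float] | None = None
    best_params = SVMParams()
    for C in C_grid:
        for gamma in gamma_grid:
            svm = SVMParams(C=C, gamma=gamma)
            dv = _oof_decision_values(matrix.X, matrix.y, cv, svm)
            rep = metrics_from_predictions(matrix.y, (dv >= 0.0).astype(int))
            key = (rep.oa, -C, -gamma)  # prefer smaller C/gamma on ties
            if best is None or key > best:
                best = key
                best_params = svm
    assert best is not None
    return best_params, best[0]


@dataclass
class GridSearchResult:
    """Per-cell IFS summaries of the (g, δ) search."""

    table: pd.DataFrame  # columns: g, delta, best_size, best_OA, best_AA
    best_cell: tuple[int, int, int]  # (g, delta, subset size)
    best_params: PseAACParams
    best_result: IFSResult

    @property
    def n_cells(self) -> int:
        return len(self.table)


def grid_search(
    records: Sequence[ProteinRecord],
    labels: Mapping[str, int],
    g_range: Iterable[int] = range(0, 10),
    delta_range: Iterable[int] = range(1, 11),
    cv: CVConfig | None = None,
    table: PhysChemTable | None = None,
    svm: SVMParams | None = None,
    criterion: str = "OA",
    max_subset_size: int | None = None,
    stride: int = 1,
) -> GridSearchResult:
    """Search the (g, δ) grid; each cell runs F-ranking plus IFS with CV.

    The default ranges reproduce the standard 10 × 10 = 100-cell grid.
    Before any compute, every record is checked against the largest cell's
    minimum length; offenders are reported together. IFS uses
    fold-internal ranking (see :func:`cv_incremental_feature_selection`).
    The winning cell maximizes the cross-validated criterion, ties
    resolved toward the smallest subset size, then the smaller (g, δ).
    """
    cv = cv or CVConfig()
    table = table or default_table()
    svm = svm or SVMParams()
    g_values = sorted(set(int(g) for g in g_range))
    d_values = sorted(set(int(d) for d in delta_range))
    if not g_values or not d_values:
        raise ConfigError("empty g or delta range")

    need = max(max(g_values) + 2, max(d_values) + 1)
    short = [(r.id, r.length) for r in records if r.length < need]
    if short:
        raise SequenceTooShortError(
            f"grid needs length >= {need}; too short: "
            + ", ".join(f"{rid} (L={L})" for rid, L in short)
        )

    rows = []
    best_key: tuple | None = None
    best_cell = None
    best_params = None
    best_result = None
    for g in g_values:
        for d in d_values:
            params = PseAACParams(g=g, delta=d)
            matrix = encode_matrix(records, labels, params, table)
            ifs = cv_incremental_feature_selection(
                matrix, cv, svm, criterion=criterion,
                max_size=max_subset_size, stride=stride,
            )
            crit_val = getattr(ifs.best_report, criterion.lower())
            rows.append(
                {
                    "g": g,
                    "delta": d,
                    "best_size": ifs.best_size,
                    "best_OA": ifs.best_report.oa,
                    "best_AA": ifs.best_report.aa,
                }
            )
            key = (crit_val, -ifs.best_size, -g, -d)
            if best_key is None or key > best_key:
                best_key = key
                best_cell = (g, d, ifs.best_size)
                best_params = params
                best_result = ifs
            logger.info(
                "grid cell (g=%d, delta=%d): best size %d, %s",
                g, d, ifs.best_size, ifs.best_report.format_row(),
            )
    assert best_cell is not None and best_params is not None and best_result is not None
    return GridSearchResult(
        table=pd.DataFrame(rows),
        best_cell=best_cell,
        best_params=best_params,
        best_result=best_result,
    )


@dataclass
class TrainedModel:
    """A fitted predictor: encoder params, feature subset, scaler+SVM, threshold."""

    params: PseAACParams
    selected_features: list[str]
    pipeline: Pipeline
    threshold: float
    table: PhysChemTable
    provenance: dict = field(default_factory=dict)

    def _encode_one(self, record: ProteinRecord) -> np.ndarray:
        from .features import encode

        vec = encode(record, self.params, self.table)
        frame = pd.Series(vec.values, index=vec.names)
        return frame[self.selected_features].to_numpy(dtype=float)

    def predict(self, records: Sequence[ProteinRecord]) -> pd.DataFrame:
        """Per-record decision values and labels; per-record error entries.

        A record that cannot be encoded (too short for the trained
        parameters, invalid residues) gets an ``error`` message and NaN
        outputs; other records are unaffected.
        """
        rows = []
        ok_idx, ok_feats = [], []
        for k, rec in enumerate(records):
            reason = validate_sequence(rec.sequence, self.params.min_length)
            if reason is not None:
                rows.append(
                    {"id": rec.id, "decision_value": np.nan, "label": pd.NA, "error": reason}
                )
                continue
            rows.append({"id": rec.id, "decision_value": np.nan, "label": pd.NA, "error": ""})
            ok_idx.append(k)
            ok_feats.append(self._encode_one(rec))
        frame = pd.DataFrame(rows, columns=["id", "decision_value", "label", "error"])
        if ok_idx:
            dv = self.pipeline.decision_function(np.vstack(ok_feats))
            frame.loc[ok_idx, "decision_value"] = dv
            frame.loc[ok_idx, "label"] = (dv >= self.threshold).astype(int)
        return frame

    def save(self, path: str | Path) -> None:
        """Persist as a zip archive: JSON manifest + serialized SVM state."""
        manifest = {
            "format_version": 1,
            "software_version": __version__,
            "params": {
                "g": self.params.g,
                "delta": self.params.delta,
                "property_subset": list(self.params.property_subset),
            },
            "selected_features": self.selected_features,
            "threshold": self.threshold,
            "property_names": list(self.table.property_names),
            "property_values": self.table.original.tolist(),
            "provenance": self.provenance,
        }
        buf = io.BytesIO()
        joblib.dump(self.pipeline, buf)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
            zf.writestr("svm.joblib", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            pipeline = joblib.load(io.BytesIO(zf.read("svm.joblib")))
        table = PhysChemTable(
            property_names=tuple(manifest["property_names"]),
            original=np.array(manifest["property_values"]),
        )
        params = PseAACParams(
            g=manifest["params"]["g"],
            delta=manifest["params"]["delta"],
            property_subset=tuple(manifest["params"]["property_subset"]),
        )
        return cls(
            params=params,
            selected_features=list(manifest["selected_features"]),
            pipeline=pipeline,
            threshold=float(manifest["threshold"]),
            table=table,
            provenance=dict(manifest.get("provenance", {})),
        )


def train_final(
    records: Sequence[ProteinRecord],
    labels: Mapping[str, int],
    params: PseAACParams,
    selected_features: Sequence[str],
    svm: SVMParams | None = None,
    threshold: float = 0.0,
    table: PhysChemTable | None = None,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit scaling and SVM on all data with the chosen feature subset."""
    table = table or default_table()
    svm = svm or SVMParams()
    known = set(feature_names(params, table))
    unknown = [f for f in selected_features if f not in known]
    if unknown:
        raise ConfigError(f"unknown feature name(s) for these params: {unknown[:5]}")
    matrix = encode_matrix(records, labels, params, table)
    X = matrix.X[list(selected_features)].to_numpy(dtype=float)
    pipeline = _make_pipeline(svm)
    pipeline.fit(X, matrix.y)
    return TrainedModel(
        params=params,
        selected_features=list(selected_features),
        pipeline=pipeline,
        threshold=float(threshold),
        table=table,
        provenance=provenance or {},
    )
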