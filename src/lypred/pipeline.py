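"""End-to-end run orchestration with reproducibility plumbing.

A run executes: encode → ANOVA ranking → IFS (stratified 5-fold CV) →
optional (g, δ) grid search → jackknife verification of the chosen
subset → decision-threshold tuning → final model fit on all data. Every
artifact is written under one output directory together with the
effective configuration and its hash, so reruns with an identical config
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classifier import (
    CVConfig,
    SVMParams,
    cross_validated_scores,
    cv_incremental_feature_selection,
    grid_search,
    train_final,
    tune_threshold,
)
from .errors import ConfigError, SequenceTooShortError
from .features import PseAACParams, encode_matrix
from .physchem import PhysChemTable, default_table
from .seqio import DEFAULT_MIN_LENGTH, read_fasta, read_labels
from .selection import anova_f_scores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a full pipeline run."""

    fasta: str
    labels: str
    outdir: str
    g: int = 4
    delta: int = 7
    run_grid: bool = False
    g_min: int = 0
    g_max: int = 9
    delta_min: int = 1
    delta_max: int = 10
    n_folds: int = 5
    seed: int = 0
    min_length: int = DEFAULT_MIN_LENGTH
    threshold_criterion: str = "AA"
    ifs_criterion: str = "OA"
    max_subset_size: int | None = None
    stride: int = 1
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Paths of the artifact bundle plus the headline evaluation."""

    outdir: Path
    artifacts: dict[str, Path]
    evaluation: dict
    best_features: list[str] = field(repr=False, default_factory=list)


def run_pipeline(config: RunConfig, table: PhysChemTable | None = None) -> RunResult:
    """Execute the full protocol; see module docstring for the stages.

    Pre-flight validation (inputs readable, sequences long enough for the
    requested parameters) happens before any output file is written.
    """
    table = table or default_table()
    cv = CVConfig(n_folds=config.n_folds, seed=config.seed)
    svm = SVMParams(C=config.svm_C, gamma=config.svm_gamma)

    # ---- pre-flight: read and validate everything before writing anything
    records = read_fasta(config.fasta, min_length=config.min_length)
    labels = read_labels(config.labels)
    if config.run_grid:
        need = max(config.g_max + 2, config.delta_max + 1)
    else:
        need = PseAACParams(g=config.g, delta=config.delta).min_length
    short = [(r.id, r.length) for r in records if r.length < need]
    if short:
        raise SequenceTooShortError(
            f"parameters require length >= {need}; too short: "
            + ", ".join(f"{rid} (L={L})" for rid, L in short)
        )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _path(name: str) -> Path:
        p = outdir / name
        artifacts[name] = p
        return p

    with open(_path("run_config.json"), "w") as out:
        out.write(config.to_json() + "\n")

    grid_result = None
    if config.run_grid:
        logger.info("grid search over g=%d..%d, delta=%d..%d",
                    config.g_min, config.g_max, config.delta_min, config.delta_max)
        grid_result = grid_search(
            records, labels,
            g_range=range(config.g_min, config.g_max + 1),
            delta_range=range(config.delta_min, config.delta_max + 1),
            cv=cv, table=table, svm=svm, criterion=config.ifs_criterion,
            max_subset_size=config.max_subset_size, stride=config.stride,
        )
        grid_result.table.to_csv(_path("grid.tsv"), sep="\t", index=False)
        params = grid_result.best_params
        logger.info("grid best cell: g=%d delta=%d size=%d", *grid_result.best_cell)
    else:
        params = PseAACParams(g=config.g, delta=config.delta)

    matrix = encode_matrix(records, labels, params, table)
    matrix.to_tsv(_path("features.tsv"))

    ranking = anova_f_scores(matrix)
    ranking.to_frame().to_csv(_path("ranking.tsv"), sep="\t", index=False)

    if grid_result is not None:
        ifs = grid_result.best_result
    else:
        ifs = cv_incremental_feature_selection(
            matrix, cv, svm, criterion=config.ifs_criterion,
            max_size=config.max_subset_size, stride=config.stride,
        )
    ifs.curve_frame().to_csv(_path("ifs_curve.tsv"), sep="\t", index=False)
    best_features = ifs.best_features
    logger.info("IFS best subset: %d features, %s",
                ifs.best_size, ifs.best_report.format_row())

    # jackknife verification of the chosen subset, then threshold tuning
    from .features import FeatureMatrix

    sub = FeatureMatrix(X=matrix.X[best_features], y=matrix.y)
    jk = CVConfig(seed=config.seed, jackknife=True)
    dv = cross_validated_scores(sub, jk, svm)
    tuned = tune_threshold(dv, matrix.y, criterion=config.threshold_criterion)
    logger.info("jackknife @ tuned threshold %.6g: %s",
                tuned.threshold, tuned.report.format_row())

    evaluation = {
        "params": {"g": params.g, "delta": params.delta},
        "n_selected_features": len(best_features),
        "cv_best": ifs.best_report.to_dict(),
        "jackknife_at_threshold": tuned.report.to_dict(),
        "threshold": tuned.threshold,
        "threshold_criterion": config.threshold_criterion.upper(),
        "seed": config.seed,
        "config_hash": config.config_hash,
        "software_version": __version__,
    }
    with open(_path("evaluation.json"), "w") as out:
        json.dump(evaluation, out, indent=2, sort_keys=True)
        out.write("\n")

    model = train_final(
        records, labels, params, best_features, svm=svm,
        threshold=tuned.threshold, table=table,
        provenance={
            "seed": config.seed,
            "cv": asdict(cv),
            "config_hash": config.config_hash,
            "software_version": __version__,
        },
    )
    model.save(_path("model.zip"))
    return RunResult(
        outdir=outdir, artifacts=artifacts, evaluation=evaluation,
        best_features=list(best_features),
    )
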