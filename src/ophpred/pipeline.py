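"""End-to-end pipeline: curate -> split -> embed -> fit -> predict -> evaluate.

Every intermediate artifact is persisted under a run directory (curated
labels, split file, embedding cache, fitted model, predictions, evaluation
report) together with a manifest of stage counts, and one pipeline-level
seed drives every stochastic stage, so a rerun with the same configuration
reproduces the split file and predictions byte for byte with deterministic
embedding backends.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from . import io as oio
from .curation import curate_optimal_ph
from .data import CuratedDataset
from .embed import embed_dataset, get_embedder
from .errors import MissingInputError, ValidationError
from .evaluation import DEFAULT_DELTAS, EvalReport, evaluate
from .regression import (
    RegressorSpec,
    default_gbt_grid,
    default_knn_grid,
    fit,
    fit_best,
)
from .splitting import (
    DistanceMatrix,
    SplitAssignment,
    homology_split,
    random_split,
    write_split,
)

logger = logging.getLogger("ophpred")


@dataclass
class PipelineConfig:
    fasta: str
    measurements: str
    out_dir: str
    strategy: str = "random"  # random | homology
    eps: float = 0.4
    min_samples: int = 5
    validation_fraction: float = 0.25
    distance_matrix: Optional[str] = None  # precomputed, for homology strategy
    embedder: str = "onehot"
    max_length: int = 5000
    model: str = "knn"  # knn | gbt | naive_median
    grid: Optional[list[dict[str, Any]]] = None
    n_folds: int = 5
    deltas: tuple[float, ...] = DEFAULT_DELTAS
    superkingdom: Optional[str] = None  # annotation table for stratified metrics
    std_threshold: float = 1.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        if not os.path.exists(path):
            raise MissingInputError(f"config file not found: {path}")
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml

                raw = yaml.safe_load(fh)
            else:
                raw = json.load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "deltas" in raw:
            raw["deltas"] = tuple(float(d) for d in raw["deltas"])
        return cls(**raw)


@dataclass
class PipelineResult:
    report: EvalReport
    split: SplitAssignment
    paths: dict[str, str]
    counts: dict[str, Any] = field(default_factory=dict)


def _build_grid(config: PipelineConfig) -> list[RegressorSpec]:
    if config.grid:
        return [
            RegressorSpec.make(config.model, seed=config.seed, **entry)
            for entry in config.grid
        ]
    if config.model == "knn":
        return default_knn_grid(seed=config.seed)
    if config.model == "gbt":
        return default_gbt_grid(seed=config.seed)
    return [RegressorSpec.make("naive_median", seed=config.seed)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and persist every intermediate artifact.

    The random and homology strategies are supported end to end here; the
    PFAM hold-out and EC splits produce many splits/folds rather than one
    train/validation pair and are driven through their dedicated functions
    (:func:`ophpred.splitting.pfam_holdout_splits`,
    :func:`ophpred.splitting.ec_split`) or the ``ophpred split`` subcommand.
    """
    for path in (config.fasta, config.measurements):
        if not os.path.exists(path):
            raise MissingInputError(f"input file not found: {path}")
    if config.strategy not in ("random", "homology"):
        raise ValidationError(
            f"run_pipeline supports strategies 'random' and 'homology', "
            f"not {config.strategy!r}"
        )
    os.makedirs(config.out_dir, exist_ok=True)
    paths = {
        name: os.path.join(config.out_dir, fname)
        for name, fname in [
            ("labels", "curated_labels.csv"),
            ("split", "split.csv"),
            ("embeddings", "embeddings.csv"),
            ("model", "model.joblib"),
            ("predictions", "predictions.csv"),
            ("report", "report.csv"),
            ("manifest", "manifest.json"),
        ]
    }
    counts: dict[str, Any] = {}

    records = oio.read_fasta(config.fasta)
    counts["records_read"] = len(records)
    table = oio.read_measurement_table(config.measurements)
    counts["measurements_read"] = len(table)
    dataset, curation_log = curate_optimal_ph(
        table, records, std_threshold=config.std_threshold
    )
    counts["curated"] = len(dataset)
    counts["dropped_high_std"] = len(curation_log.dropped_high_std)
    oio.write_labels(dataset.labels, paths["labels"])
    logger.info(
        "curated %d/%d ids (%d dropped by std filter)",
        len(dataset), curation_log.n_input_ids, counts["dropped_high_std"],
    )

    if config.strategy == "random":
        split = random_split(
            dataset, validation_fraction=config.validation_fraction, seed=config.seed
        )
        counts["orphans"] = None
    else:
        distance = None
        if config.distance_matrix:
            ids, D = oio.read_matrix(config.distance_matrix)
            distance = DistanceMatrix(ids=ids, D=D)
            order = {rid: i for i, rid in enumerate(ids)}
            missing = [rid for rid in dataset.ids if rid not in order]
            if missing:
                raise ValidationError(
                    f"distance matrix missing dataset ids: {missing[:5]}"
                )
            keep = [order[rid] for rid in dataset.ids]
            distance = DistanceMatrix(
                ids=list(dataset.ids), D=D[np.ix_(keep, keep)]
            )
        split, clusters = homology_split(
            dataset,
            eps=config.eps,
            min_samples=config.min_samples,
            validation_fraction=config.validation_fraction,
            seed=config.seed,
            distance=distance,
        )
        counts["clusters"] = clusters.n_clusters
        counts["orphans"] = (
            0
            if clusters.orphan_cluster_index is None
            else sum(
                1
                for c in clusters.assignments.values()
                if c == clusters.orphan_cluster_index
            )
        )
    write_split(split, paths["split"])
    counts["train"] = len(split.train_ids)
    counts["validation"] = len(split.validation_ids)
    logger.info("split: %d train / %d validation", counts["train"], counts["validation"])

    spec = get_embedder(config.embedder, max_length=config.max_length)
    matrix, embed_log = embed_dataset(
        dataset.records, spec, cache_path=paths["embeddings"]
    )
    counts["truncated"] = embed_log.n_truncated

    train_ids = sorted(split.train_ids)
    val_ids = sorted(split.validation_ids)
    X_train = matrix.rows(train_ids)
    y_train = np.array([dataset.labels[i] for i in train_ids])
    X_val = matrix.rows(val_ids)
    y_val = np.array([dataset.labels[i] for i in val_ids])
    from .embed import EmbeddingMatrix

    train_matrix = EmbeddingMatrix(
        ids=train_ids, X=X_train, embedder_name=matrix.embedder_name
    )
    grid = _build_grid(config)
    if len(grid) == 1:
        model = fit(grid[0], train_matrix, y_train)
        cv_table = None
    else:
        model, cv = fit_best(
            grid, train_matrix, y_train, n_folds=config.n_folds, seed=config.seed
        )
        cv_table = {str(k): v for k, v in cv.items()}
    model.save(paths["model"])
    counts["model"] = str(model.spec)

    y_pred = model.predict(X_val)
    with open(paths["predictions"], "w") as fh:
        fh.write("id,ph_true,ph_pred\n")
        for rid, yt, yp in zip(val_ids, y_val, y_pred):
            fh.write(f"{rid},{yt!r},{float(yp)!r}\n")

    groups = None
    if config.superkingdom:
        kingdom_of = oio.read_annotation_table(
            config.superkingdom, "superkingdom", multi=False
        )
        groups = [kingdom_of.get(rid, "unclassified") for rid in val_ids]
    report = evaluate(
        y_val,
        y_pred,
        train_median=float(np.median(y_train)),
        deltas=config.deltas,
        groups=groups,
    )
    report.write(paths["report"])

    manifest = {
        "counts": counts,
        "paths": {k: os.path.basename(v) for k, v in paths.items()},
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if not isinstance(v, dict)
        },
    }
    if cv_table:
        manifest["cv_table"] = cv_table
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(report=report, split=split, paths=paths, counts=counts)
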