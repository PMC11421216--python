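"""Train/validation split strategies that control sequence-similarity leakage.

Random splitting ignores homology and therefore overestimates performance
when near-identical sequences land on both sides. The homology split instead
clusters sequences by normalized pairwise identity (DBSCAN on the 1 - identity
distance matrix, with all noise points merged into a single "orphan" cluster)
and assigns whole clusters to one side, packing them to approximate the 3:1
train:validation ratio. PFAM hold-out withholds every sequence carrying a
given family annotation; the EC split separates hydrolases (top-level EC
class 3) from the rest, discarding bifunctional sequences. Training-set
enrichment adds new sequences while keeping them at distance > eps from the
existing validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from sklearn.cluster import DBSCAN

from .data import CuratedDataset, ProteinRecord
from .errors import ValidationError


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of identity scores normalized to [0, 1]."""

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValidationError("similarity matrix shape does not match ids")
        if not np.allclose(self.S, self.S.T, atol=1e-9):
            raise ValidationError("similarity matrix is not symmetric")
        if self.S.min() < -1e-9 or self.S.max() > 1 + 1e-9:
            raise ValidationError("similarity entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValidationError("similarity diagonal must be 1 (self-identity)")


@dataclass
class DistanceMatrix:
    """Elementwise 1 - similarity; zero diagonal."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if self.D.min() < -1e-9 or self.D.max() > 1 + 1e-9:
            raise ValidationError("distance entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.D), 0.0):
            raise ValidationError("distance diagonal must be 0")


@dataclass
class ClusterAssignment:
    """id -> cluster index; noise points share one orphan cluster."""

    assignments: dict[str, int]
    orphan_cluster_index: Optional[int] = None

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for rid, c in self.assignments.items():
            out.setdefault(c, []).append(rid)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))


@dataclass
class SplitAssignment:
    """Disjoint train/validation id sets, plus explicitly discarded ids."""

    train_ids: set[str]
    validation_ids: set[str]
    discarded_ids: set[str] = field(default_factory=set)
    folds: Optional[list[set[str]]] = None

    def __post_init__(self) -> None:
        overlap = self.train_ids & self.validation_ids
        if overlap:
            raise ValidationError(
                f"train and validation overlap: {sorted(overlap)[:5]}"
            )

    @property
    def all_ids(self) -> set[str]:
        return self.train_ids | self.validation_ids | self.discarded_ids


def random_split(
    dataset: CuratedDataset, validation_fraction: float = 0.25, seed: int = 0
) -> SplitAssignment:
    """Seeded random split with |validation| = round(n * fraction)."""
    if not (0.0 < validation_fraction < 1.0):
        raise ValidationError("validation_fraction must lie in (0, 1)")
    ids = dataset.ids
    if len(ids) < 2:
        raise ValidationError("random_split needs at least 2 records")
    n_val = int(round(len(ids) * validation_fraction))
    n_val = min(max(n_val, 1), len(ids) - 1)
    rng = np.random.RandomState(seed)
    order = rng.permutation(len(ids))
    val = {ids[i] for i in order[:n_val]}
    return SplitAssignment(train_ids=set(ids) - val, validation_ids=val)


# Global alignment scored match=1 / mismatch=0 / gap=0: the optimal score is
# the maximum number of identical aligned residue pairs, i.e. the length of
# the longest common subsequence.
_aligner = Align.PairwiseAligner(
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=0.0,
    extend_gap_score=0.0,
    mode="global",
)


def identity_score(a: str, b: str) -> float:
    """Identity count from an optimal global alignment, over the shorter length."""
    if not a or not b:
        raise ValidationError("identity_score: empty sequence")
    return float(_aligner.score(a, b)) / min(len(a), len(b))


def pairwise_similarity(records: Sequence[ProteinRecord]) -> SimilarityMatrix:
    """All-vs-all normalized identity matrix.

    S[a, b] = (identical aligned residue pairs in the optimal global
    alignment) / min(len(a), len(b)). Diagonal is 1 by construction. For
    large datasets a precomputed matrix can be loaded with
    :func:`ophpred.io.read_matrix` instead.
    """
    if len(records) < 2:
        raise ValidationError("pairwise_similarity needs at least 2 records")
    n = len(records)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = identity_score(
                records[i].sequence, records[j].sequence
            )
    return SimilarityMatrix(ids=[r.id for r in records], S=S)


def similarity_to_distance(sim: SimilarityMatrix) -> DistanceMatrix:
    """D = 1 - S elementwise, diagonal forced to zero."""
    D = 1.0 - sim.S
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ids=list(sim.ids), D=D)


def density_cluster(
    dist: DistanceMatrix, eps: float, min_samples: int = 5
) -> ClusterAssignment:
    """DBSCAN over a precomputed distance matrix, with an orphan cluster.

    Core points have at least ``min_samples`` neighbors (self included)
    within ``eps``; clusters are maximal density-connected sets. All noise
    points are merged into one extra orphan cluster rather than dropped, so
    every id is assigned. With ``min_samples=1`` the result equals the
    connected components of the graph with edges {(a, b): D[a, b] <= eps},
    which is the setting under which the leakage guarantee (cross-split
    distance > eps) holds exactly.
    """
    if eps <= 0 or eps >= 1:
        raise ValidationError("eps must lie in (0, 1)")
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(
        dist.D
    ).labels_
    orphan_index: Optional[int] = None
    if (labels == -1).any():
        orphan_index = int(labels.max()) + 1
        labels = labels.copy()
        labels[labels == -1] = orphan_index
    return ClusterAssignment(
        assignments={rid: int(c) for rid, c in zip(dist.ids, labels)},
        orphan_cluster_index=orphan_index,
    )


def clusters_to_split(
    clusters: ClusterAssignment,
    validation_fraction: float = 0.25,
    seed: int = 0,
) -> SplitAssignment:
    """Pack whole clusters into validation until the target fraction is reached.

    Clusters are shuffled by seed and moved to validation greedily until
    |validation| >= round(n * fraction); the remainder forms the training set.
    The achieved fraction is therefore within one assigned-cluster size of
    the target. A single cluster covering everything admits no valid split.
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ValidationError("validation_fraction must lie in (0, 1)")
    by_cluster = clusters.clusters()
    n = len(clusters.assignments)
    if len(by_cluster) < 2:
        raise ValidationError(
            "cannot split: a single cluster covers the whole dataset"
        )
    target = max(1, int(round(n * validation_fraction)))
    rng = np.random.RandomState(seed)
    cluster_ids = sorted(by_cluster)
    rng.shuffle(cluster_ids)
    validation: set[str] = set()
    for c in cluster_ids:
        if len(validation) >= target:
            break
        members = by_cluster[c]
        # never let validation swallow the entire dataset
        if len(validation) + len(members) >= n:
            continue
        validation.update(members)
    if not validation:
        # every candidate would have swallowed the dataset except the ones
        # left for train; fall back to the smallest cluster
        smallest = min(cluster_ids, key=lambda c: len(by_cluster[c]))
        validation.update(by_cluster[smallest])
    train = set(clusters.assignments) - validation
    return SplitAssignment(train_ids=train, validation_ids=validation)


def homology_split(
    dataset: CuratedDataset,
    eps: float,
    min_samples: int = 5,
    validation_fraction: float = 0.25,
    seed: int = 0,
    distance: Optional[DistanceMatrix] = None,
) -> tuple[SplitAssignment, ClusterAssignment]:
    """Convenience path: similarity -> distance -> cluster -> packed split."""
    if distance is None:
        distance = similarity_to_distance(pairwise_similarity(dataset.records))
    clusters = density_cluster(distance, eps=eps, min_samples=min_samples)
    split = clusters_to_split(
        clusters, validation_fraction=validation_fraction, seed=seed
    )
    return split, clusters


@dataclass
class PfamHoldout:
    splits: list[tuple[str, SplitAssignment]]
    skipped: list[str]


def pfam_holdout_splits(
    dataset: CuratedDataset, pfam_annotations: Mapping[str, Sequence[str]]
) -> PfamHoldout:
    """One hold-out split per distinct PFAM accession.

    Validation = every id carrying the accession; train = everything else,
    including unannotated ids. Accessions whose validation set would be empty
    or the whole dataset are skipped and reported.
    """
    all_ids = set(dataset.ids)
    by_pfam: dict[str, set[str]] = {}
    for rid, accs in pfam_annotations.items():
        if rid not in all_ids:
            continue
        for acc in accs:
            by_pfam.setdefault(acc, set()).add(rid)
    splits: list[tuple[str, SplitAssignment]] = []
    skipped: list[str] = []
    for acc in sorted(by_pfam):
        val = by_pfam[acc]
        if not val or val == all_ids:
            skipped.append(acc)
            continue
        splits.append(
            (acc, SplitAssignment(train_ids=all_ids - val, validation_ids=val))
        )
    return PfamHoldout(splits=splits, skipped=skipped)


def parse_ec_class(code: str, id: str = "?") -> int:
    """Top-level EC class from a full or truncated code ('3.2.1.4', '3.-')."""
    head = code.strip().split(".")[0]
    try:
        cls = int(head)
    except ValueError:
        raise ValidationError(f"id {id!r}: unparseable EC code {code!r}") from None
    if cls < 1:
        raise ValidationError(f"id {id!r}: invalid EC class in {code!r}")
    return cls


@dataclass
class ECSplit:
    """Hydrolase folds plus the nonhydrolase training pool."""

    hydrolase_folds: list[set[str]]
    nonhydrolase_train: set[str]
    discarded: set[str]


def ec_split(
    dataset: CuratedDataset,
    ec_annotations: Mapping[str, Sequence[str]],
    n_folds: int = 5,
    seed: int = 0,
) -> ECSplit:
    """EC-based split: hydrolases (class 3) vs the rest.

    Ids annotated with class 3 and any other class (bifunctional) are
    discarded, as are ids without any EC annotation. Pure hydrolases are
    partitioned into ``n_folds`` near-equal seeded folds (hydrolase-specific
    models cross-validate over them; nonhydrolase-specific models train on
    the rest and validate on each fold).
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    hydro: list[str] = []
    nonhydro: set[str] = set()
    discarded: set[str] = set()
    for rid in dataset.ids:
        codes = ec_annotations.get(rid)
        if not codes:
            discarded.add(rid)
            continue
        classes = {parse_ec_class(c, rid) for c in codes}
        if 3 in classes and classes != {3}:
            discarded.add(rid)  # bifunctional: hydrolase + something else
        elif classes == {3}:
            hydro.append(rid)
        else:
            nonhydro.add(rid)
    if len(hydro) < n_folds:
        raise ValidationError(
            f"only {len(hydro)} hydrolase ids for {n_folds} folds"
        )
    rng = np.random.RandomState(seed)
    order = rng.permutation(len(hydro))
    folds: list[set[str]] = [set() for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].add(hydro[idx])
    return ECSplit(
        hydrolase_folds=folds, nonhydrolase_train=nonhydro, discarded=discarded
    )


def enrich_training(
    split: SplitAssignment,
    new_dataset: CuratedDataset,
    distance_to_validation: Optional[Callable[[str, str], float]] = None,
    eps: Optional[float] = None,
) -> SplitAssignment:
    """Add new sequences to the training set, guarding the validation set.

    With ``eps`` given, a new id joins train only when its distance to every
    validation id exceeds ``eps`` (homology-guarded enrichment). With ``eps``
    absent (random-split mode) all new ids join train. The validation set is
    never changed.
    """
    new_ids = set(new_dataset.ids)
    collisions = new_ids & split.all_ids
    if collisions:
        raise ValidationError(
            f"enrichment ids collide with existing split: {sorted(collisions)[:5]}"
        )
    if eps is not None and distance_to_validation is None:
        raise ValidationError("eps given but no distance function supplied")
    admitted: set[str] = set()
    for rid in sorted(new_ids):
        if eps is None:
            admitted.add(rid)
        elif all(
            distance_to_validation(rid, vid) > eps for vid in split.validation_ids
        ):
            admitted.add(rid)
    return SplitAssignment(
        train_ids=split.train_ids | admitted,
        validation_ids=set(split.validation_ids),
        discarded_ids=set(split.discarded_ids),
        folds=split.folds,
    )


def write_split(split: SplitAssignment, path: str) -> None:
    """Persist a split as (id, role, fold) delimited text, sorted for determinism."""
    fold_of: dict[str, int] = {}
    if split.folds:
        for k, fold in enumerate(split.folds):
            for rid in fold:
                fold_of[rid] = k
    with open(path, "w") as fh:
        fh.write("id,role,fold\n")
        for rid in sorted(split.train_ids):
            fh.write(f"{rid},train,{fold_of.get(rid, '')}\n")
        for rid in sorted(split.validation_ids):
            fh.write(f"{rid},validation,{fold_of.get(rid, '')}\n")
        for rid in sorted(split.discarded_ids):
            fh.write(f"{rid},discarded,\n")


def read_split(path: str) -> SplitAssignment:
    import pandas as pd

    df = pd.read_csv(path)
    train = set(df.loc[df["role"] == "train", "id"].astype(str))
    val = set(df.loc[df["role"] == "validation", "id"].astype(str))
    disc = set(df.loc[df["role"] == "discarded", "id"].astype(str))
    folds = None
    if "fold" in df.columns and df["fold"].notna().any():
        sub = df[df["fold"].notna()]
        n = int(sub["fold"].max()) + 1
        folds = [set() for _ in range(n)]
        for rid, k in zip(sub["id"].astype(str), sub["fold"].astype(int)):
            folds[k].add(rid)
    return SplitAssignment(
        train_ids=train, validation_ids=val, discarded_ids=disc, folds=folds
    )
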