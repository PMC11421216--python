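"""Fixed-length sequence embeddings behind one adapter contract.

The fully implemented backend is the averaged one-hot encoding: a sequence
maps to the 20-vector of its canonical residue frequencies (a composition
vector). Deep language-model embedders plug in through the same
:class:`EmbedderSpec` contract — a deterministic per-sequence transform with
a declared output dimension — and precomputed embedding tables can be
imported from delimited text, so the pipeline runs offline with or without
any deep model installed. Sequences longer than ``max_length`` (default
5000) are truncated to their first ``max_length`` residues before embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .data import CANONICAL_AA, ProteinRecord
from .errors import MissingInputError, ValidationError
from .io import read_embedding_table, write_embedding_table

DEFAULT_MAX_LENGTH = 5000

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


def truncate_sequence(sequence: str, max_length: int = DEFAULT_MAX_LENGTH) -> str:
    """First ``max_length`` residues; shorter sequences pass unchanged."""
    if max_length < 1:
        raise ValidationError("max_length must be >= 1")
    return sequence[:max_length]


def onehot_embed(sequence: str, unknown_channel: bool = False) -> np.ndarray:
    """Averaged one-hot encoding over residue positions.

    Each position contributes a one-hot row over the canonical alphabet
    ACDEFGHIKLMNPQRSTVWY; rows are averaged over all positions, so the result
    is the residue-composition vector. Noncanonical symbols contribute an
    all-zero row by default (they count in the denominator, so entries sum to
    the canonical fraction); with ``unknown_channel`` a 21st component
    collects them instead.
    """
    if not sequence:
        raise ValidationError("onehot_embed: empty sequence")
    d = 21 if unknown_channel else 20
    v = np.zeros(d)
    for c in sequence.upper():
        i = _AA_INDEX.get(c)
        if i is not None:
            v[i] += 1.0
        elif unknown_channel:
            v[20] += 1.0
    return v / len(sequence)


@dataclass
class EmbedderSpec:
    """Adapter contract: a named deterministic sequence -> d-vector transform."""

    name: str
    d: int
    transform: Callable[[str], np.ndarray]
    max_length: int = DEFAULT_MAX_LENGTH

    def __call__(self, sequence: str) -> np.ndarray:
        out = np.asarray(self.transform(sequence), dtype=float)
        if out.shape != (self.d,):
            raise ValidationError(
                f"embedder {self.name!r} returned shape {out.shape}, expected ({self.d},)"
            )
        if not np.all(np.isfinite(out)):
            raise ValidationError(f"embedder {self.name!r} returned non-finite values")
        return out


@dataclass
class EmbeddingMatrix:
    """n x d matrix with row order matching ids."""

    ids: list[str]
    X: np.ndarray
    embedder_name: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValidationError("embedding matrix shape does not match ids")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("embedding matrix contains non-finite values")

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        index = {rid: i for i, rid in enumerate(self.ids)}
        missing = [rid for rid in ids if rid not in index]
        if missing:
            raise ValidationError(f"ids missing from embedding matrix: {missing[:5]}")
        return self.X[[index[rid] for rid in ids]]


def onehot_spec(
    max_length: int = DEFAULT_MAX_LENGTH, unknown_channel: bool = False
) -> EmbedderSpec:
    d = 21 if unknown_channel else 20
    name = "onehot21" if unknown_channel else "onehot"
    return EmbedderSpec(
        name=name,
        d=d,
        transform=lambda s: onehot_embed(s, unknown_channel=unknown_channel),
        max_length=max_length,
    )


def esm2_spec(max_length: int = DEFAULT_MAX_LENGTH) -> EmbedderSpec:
    """ESM-2 (650M, 1280-d, mean-pooled) adapter; requires the fair-esm package."""
    try:
        import esm  # noqa: F401  (optional deep-learning backend)
        import torch
    except ImportError as exc:
        raise MissingInputError(
            "the 'esm2' embedder requires the optional fair-esm (and torch) "
            "packages; install fair-esm or use --embedder onehot / import"
        ) from exc

    model, alphabet = esm.pretrained.esm2_t33_650M_UR50D()
    model.eval()
    converter = alphabet.get_batch_converter()

    def transform(sequence: str) -> np.ndarray:
        with torch.no_grad():
            _, _, tokens = converter([("q", sequence)])
            reps = model(tokens, repr_layers=[33])["representations"][33]
        return reps[0, 1 : len(sequence) + 1].mean(0).numpy()

    return EmbedderSpec(
        name="esm2_t33_650M_mean", d=1280, transform=transform, max_length=max_length
    )


def get_embedder(name: str, max_length: int = DEFAULT_MAX_LENGTH) -> EmbedderSpec:
    if name == "onehot":
        return onehot_spec(max_length=max_length)
    if name == "onehot21":
        return onehot_spec(max_length=max_length, unknown_channel=True)
    if name == "esm2":
        return esm2_spec(max_length=max_length)
    raise ValidationError(f"unknown embedder {name!r}")


@dataclass
class EmbedLog:
    n_truncated: int = 0


def embed_dataset(
    records: Sequence[ProteinRecord],
    spec: EmbedderSpec,
    cache_path: Optional[str] = None,
) -> tuple[EmbeddingMatrix, EmbedLog]:
    """Embed records (truncating first), with an optional text-file cache.

    A cache written by a previous call is reused only when its ids match the
    request in order and the embedder name and dimension agree; any mismatch
    invalidates it and the matrix is recomputed and rewritten.
    """
    if not records:
        raise ValidationError("embed_dataset: no records")
    ids = [r.id for r in records]
    if cache_path is not None:
        cached = _try_read_cache(cache_path, ids, spec)
        if cached is not None:
            return cached, EmbedLog(n_truncated=0)
    log = EmbedLog()
    rows = []
    for rec in records:
        seq = truncate_sequence(rec.sequence, spec.max_length)
        if len(seq) < len(rec.sequence):
            log.n_truncated += 1
        rows.append(spec(seq))
    matrix = EmbeddingMatrix(ids=ids, X=np.vstack(rows), embedder_name=spec.name)
    if cache_path is not None:
        write_embedding_table(ids, matrix.X, cache_path, embedder_name=spec.name)
    return matrix, log


def _try_read_cache(
    path: str, ids: list[str], spec: EmbedderSpec
) -> Optional[EmbeddingMatrix]:
    import os

    if not os.path.exists(path):
        return None
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# embedder="):
        return None
    name = header.split("embedder=", 1)[1].split()[0]
    if name != spec.name:
        return None
    cached_ids, X = read_embedding_table(path)
    if cached_ids != ids or X.shape[1] != spec.d:
        return None
    return EmbeddingMatrix(ids=cached_ids, X=X, embedder_name=name)


def import_embeddings(path: str, embedder_name: str = "imported") -> EmbeddingMatrix:
    """Load a precomputed embedding table (id column + d numeric columns)."""
    ids, X = read_embedding_table(path)
    return EmbeddingMatrix(ids=ids, X=X, embedder_name=embedder_name)
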