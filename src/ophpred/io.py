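"""Readers and writers for the package's delimited-text interchange formats.

FASTA goes through Bio.SeqIO; tables are comma- or tab-delimited text with a
header row (dialect auto-detected by pandas). Annotation tables join multiple
PFAM/EC accessions with ";". Square matrices carry the id list as both header
row and first column.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import CuratedDataset, MeasurementTable, Observation, ProteinRecord, check_ph
from .errors import MissingInputError, ParseError, ValidationError


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise MissingInputError(f"input file not found: {path}")
    return path


def read_fasta(path: str) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the id; sequences are
    uppercased. Gap characters ("-", ".") and duplicate ids are rejected.
    """
    _require(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(path, "fasta"))
    except ValueError as exc:  # Bio raises ValueError on malformed input
        raise ParseError(f"malformed FASTA {path}: {exc}") from exc
    # Bio.SeqIO silently ignores junk before the first '>'; treat that as malformed.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"malformed FASTA {path}: line {lineno} precedes any '>' header"
                    )
                break
    for rec in parsed:
        if not rec.id:
            raise ParseError(f"malformed FASTA {path}: entry with empty header")
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        path,
        "fasta",
    )


def _sniff_sep(path: str) -> str:
    """Comma- or tab-delimited, decided from the first non-comment line."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def _read_csv_exact(path: str, **kw) -> pd.DataFrame:
    # float_precision="round_trip" keeps written repr() values bit-exact
    return pd.read_csv(
        path, sep=_sniff_sep(path), float_precision="round_trip", **kw
    )


def _read_table(path: str) -> pd.DataFrame:
    _require(path)
    try:
        df = _read_csv_exact(path, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse table {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_measurement_table(path: str) -> MeasurementTable:
    """Read raw pH observations.

    Expected columns: ``id`` plus either ``ph`` (point values) or
    ``ph_lo``/``ph_hi`` (ranges), or all three mixed row-wise; optional
    ``organism``. pH values outside [0, 14] and lo > hi rows are rejected.
    """
    df = _read_table(path)
    if "id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'id'")
    has_point = "ph" in df.columns
    has_range = "ph_lo" in df.columns and "ph_hi" in df.columns
    if not (has_point or has_range):
        raise ParseError(f"{path}: need column 'ph' or columns 'ph_lo' and 'ph_hi'")
    table = MeasurementTable()
    for row in df.itertuples(index=False):
        d = row._asdict()
        organism = d.get("organism")
        if organism is not None and pd.isna(organism):
            organism = None
        rid = str(d["id"])
        lo = d.get("ph_lo") if has_range else None
        hi = d.get("ph_hi") if has_range else None
        if has_range and not (pd.isna(lo) or pd.isna(hi)):
            table.add(Observation(id=rid, lo=float(lo), hi=float(hi), organism=organism))
        elif has_point and not pd.isna(d.get("ph")):
            table.add(Observation.point(rid, float(d["ph"]), organism=organism))
        else:
            raise ParseError(f"{path}: row for id {rid!r} has no usable pH value")
    return table


def write_measurement_table(table: MeasurementTable, path: str) -> None:
    rows = []
    for obs in table:
        rows.append(
            {
                "id": obs.id,
                "ph": obs.value if not obs.is_range else np.nan,
                "ph_lo": obs.lo if obs.is_range else np.nan,
                "ph_hi": obs.hi if obs.is_range else np.nan,
                "organism": obs.organism,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path: str) -> dict[str, float]:
    """Read an (id, ph) label table."""
    df = _read_table(path)
    for col in ("id", "ph"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out: dict[str, float] = {}
    for rid, ph in zip(df["id"], df["ph"]):
        rid = str(rid)
        if rid in out:
            raise ValidationError(f"{path}: duplicate label for id {rid!r}")
        out[rid] = check_ph(float(ph), f"label for {rid!r}")
    return out


def write_labels(labels: dict[str, float], path: str) -> None:
    pd.DataFrame({"id": list(labels), "ph": list(labels.values())}).to_csv(
        path, index=False
    )


def write_dataset(dataset: CuratedDataset, fasta_path: str, labels_path: str) -> None:
    write_fasta(dataset.records, fasta_path)
    write_labels(dataset.labels, labels_path)


def read_annotation_table(path: str, column: str, multi: bool = True) -> dict:
    """Read an id -> annotation table.

    ``column`` names the annotation column (``pfam``, ``ec`` or
    ``superkingdom``); multi-valued annotations are ";"-joined in the file and
    returned as lists when ``multi`` is true.
    """
    df = _read_table(path)
    for col in ("id", column):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out = {}
    for rid, val in zip(df["id"], df[column]):
        rid = str(rid)
        if pd.isna(val):
            continue
        if multi:
            out[rid] = [tok.strip() for tok in str(val).split(";") if tok.strip()]
        else:
            out[rid] = str(val).strip()
    return out


def write_annotation_table(annotations: dict, column: str, path: str) -> None:
    rows = []
    for rid, val in annotations.items():
        if isinstance(val, (list, tuple)):
            val = ";".join(str(v) for v in val)
        rows.append({"id": rid, column: val})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_matrix(path: str) -> tuple[list[str], np.ndarray]:
    """Read a square delimited numeric matrix with id header row and column."""
    _require(path)
    try:
        df = _read_csv_exact(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse matrix {path}: {exc}") from exc
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValidationError(f"{path}: matrix row and column ids differ")
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValidationError(f"{path}: matrix is not square")
    return ids, M


def write_matrix(ids: Sequence[str], M: np.ndarray, path: str) -> None:
    pd.DataFrame(M, index=list(ids), columns=list(ids)).to_csv(path)


def read_embedding_table(path: str) -> tuple[list[str], np.ndarray]:
    """Read precomputed embeddings: first column id, remaining d numeric columns."""
    _require(path)
    try:
        df = _read_csv_exact(path, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse embedding table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: embedding table needs an id column plus values")
    ids = [str(i) for i in df.iloc[:, 0]]
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{path}: embedding table contains non-finite values")
    return ids, X


def write_embedding_table(
    ids: Sequence[str], X: np.ndarray, path: str, embedder_name: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        if embedder_name:
            fh.write(f"# embedder={embedder_name} d={X.shape[1]}\n")
        cols = ",".join(f"e{j}" for j in range(X.shape[1]))
        fh.write(f"id,{cols}\n")
        for rid, row in zip(ids, X):
            fh.write(rid + "," + ",".join(repr(float(v)) for v in row) + "\n")
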