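"""Reading, writing and validation of synergy tables, expression matrices,
embedding stores and prediction files.

The on-disk formats are deliberately plain: delimited text for tables and an
HDF5 file with one named 2-D dataset per identifier for embedding matrices
(drug token embeddings, per-gene protein embeddings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class BridgeSynError(Exception):
    """Base class for all package errors."""


class SchemaError(BridgeSynError):
    """A required column is missing or a file is malformed."""


class RowError(BridgeSynError):
    """A specific row violates the table contract."""


class ValidationError(BridgeSynError):
    """A record violates a dataset invariant."""


class ContractError(BridgeSynError):
    """An operation was called with inconsistent arguments."""


class MissingIdError(BridgeSynError):
    """Requested identifiers are absent from a store or dataset."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynergyTriplet:
    """One (drug A, drug B, cell line) measurement with its synergy score.

    ``y`` is in dataset-native units (e.g. Loewe excess or ComboScore).
    """

    drug_a: str
    drug_b: str
    cell_line: str
    y: float
    tissue: Optional[str] = None

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValidationError(
                f"triplet has identical drugs {self.drug_a!r}; a combination "
                "requires two distinct drugs")
        if not np.isfinite(self.y):
            raise ValidationError(f"non-finite synergy score for "
                                  f"({self.drug_a}, {self.drug_b}, {self.cell_line})")

    @property
    def pair_key(self) -> tuple[str, str]:
        """Unordered drug-pair key: (A,B,CL) and (B,A,CL) are one combination."""
        return (self.drug_a, self.drug_b) if self.drug_a <= self.drug_b \
            else (self.drug_b, self.drug_a)


@dataclass
class DrugRecord:
    """A drug with an optional SMILES string and a token-embedding matrix
    (n_tokens x embedding width)."""

    id: str
    tokens: np.ndarray
    smiles: Optional[str] = None

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        if self.tokens.ndim != 2 or self.tokens.shape[0] < 1:
            raise ValidationError(
                f"drug {self.id!r}: token matrix must be 2-D with >= 1 row, "
                f"got shape {self.tokens.shape}")
        if not np.all(np.isfinite(self.tokens)):
            raise ValidationError(f"drug {self.id!r}: non-finite token entries")


@dataclass
class CellLineRecord:
    """A cell line: expression vector over L genes plus the enriched
    per-gene matrix G (L x protein-embedding width)."""

    id: str
    expression: np.ndarray
    G: np.ndarray

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64).ravel()
        self.G = np.asarray(self.G, dtype=np.float64)
        L = self.expression.shape[0]
        if L < 2:
            raise ValidationError(f"cell line {self.id!r}: needs >= 2 genes")
        if self.G.ndim != 2 or self.G.shape[0] != L:
            raise ValidationError(
                f"cell line {self.id!r}: G must be {L} x D_P, got {self.G.shape}")
        if not np.all(np.isfinite(self.G)):
            raise ValidationError(f"cell line {self.id!r}: non-finite G entries")


@dataclass
class Dataset:
    """Validated triplet collection with resolvable drug / cell-line features."""

    triplets: list[SynergyTriplet]
    drugs: dict[str, DrugRecord]
    cells: dict[str, CellLineRecord]
    allow_duplicates: bool = False

    def validate(self) -> "Dataset":
        seen: set[tuple] = set()
        for t in self.triplets:
            if t.drug_a not in self.drugs or t.drug_b not in self.drugs:
                missing = [d for d in (t.drug_a, t.drug_b) if d not in self.drugs]
                raise MissingIdError(f"unresolvable drug id(s) {missing} in triplet")
            if t.cell_line not in self.cells:
                raise MissingIdError(f"unresolvable cell line {t.cell_line!r}")
            key = t.pair_key + (t.cell_line,)
            if key in seen and not self.allow_duplicates:
                raise ValidationError(
                    f"duplicate unordered combination {key}; pass "
                    "allow_duplicates=True to keep replicate measurements")
            seen.add(key)
        return self

    def __len__(self):
        return len(self.triplets)


# ---------------------------------------------------------------------------
# table schema
# ---------------------------------------------------------------------------

@dataclass
class TableSchema:
    """Column-name mapping for synergy tables; the defaults match the files
    the synthetic generator writes."""

    drug_a: str = "drug_a"
    drug_b: str = "drug_b"
    cell_line: str = "cell_line"
    score: str = "score"
    tissue: str = "tissue"
    sep: str = ","


def read_synergy_table(path, schema: TableSchema | None = None) -> list[SynergyTriplet]:
    """Parse a delimited synergy table into triplets.

    Rows whose score is blank or non-finite are rejected and counted in a log
    message; rows violating the distinct-drug invariant raise.
    """
    schema = schema or TableSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=schema.sep, float_precision="round_trip",
                     dtype={schema.drug_a: str, schema.drug_b: str,
                            schema.cell_line: str})
    required = [schema.drug_a, schema.drug_b, schema.cell_line, schema.score]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    has_tissue = schema.tissue in df.columns

    scores = pd.to_numeric(df[schema.score], errors="coerce")
    bad_raw = df[schema.score].notna() & scores.isna()
    if bad_raw.any():
        line = int(np.flatnonzero(bad_raw.to_numpy())[0]) + 2  # 1-based + header
        raise RowError(f"{path}: unparseable score "
                       f"{df[schema.score][bad_raw].iloc[0]!r} at line {line}")
    finite = np.isfinite(scores.to_numpy(dtype=float))
    n_rejected = int((~finite).sum())
    if n_rejected:
        logger.warning("%s: rejected %d row(s) with missing/non-finite scores",
                       path, n_rejected)

    triplets = []
    for i in np.flatnonzero(finite):
        row = df.iloc[int(i)]
        tissue = row[schema.tissue] if has_tissue and pd.notna(row[schema.tissue]) else None
        triplets.append(SynergyTriplet(
            drug_a=str(row[schema.drug_a]), drug_b=str(row[schema.drug_b]),
            cell_line=str(row[schema.cell_line]), y=float(scores.iloc[int(i)]),
            tissue=tissue))
    return triplets


def write_synergy_table(triplets: Sequence[SynergyTriplet], path,
                        schema: TableSchema | None = None) -> None:
    schema = schema or TableSchema()
    df = pd.DataFrame({
        schema.drug_a: [t.drug_a for t in triplets],
        schema.drug_b: [t.drug_b for t in triplets],
        schema.cell_line: [t.cell_line for t in triplets],
        schema.score: [repr(t.y) for t in triplets],
        schema.tissue: [t.tissue if t.tissue is not None else "" for t in triplets],
    })
    df.to_csv(path, sep=schema.sep, index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, sep: str = ",") -> tuple[list[str], dict[str, np.ndarray]]:
    """Read a genes-by-cell-lines matrix.

    First column: gene ids; remaining columns: one per cell line.  Returns the
    ordered gene-id list and a map cell-line id -> expression vector (in that
    gene order).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    genes = [str(g) for g in df.index]
    dupes = pd.Index(genes)[pd.Index(genes).duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicated gene id(s) {dupes}")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: non-finite expression values")
    return genes, {str(c): values[:, j].copy() for j, c in enumerate(df.columns)}


def write_expression_matrix(genes: Sequence[str],
                            expr: dict[str, np.ndarray], path,
                            sep: str = ",") -> None:
    df = pd.DataFrame({c: v for c, v in expr.items()}, index=list(genes))
    df.index.name = "gene"
    df.to_csv(path, sep=sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# keyed embedding stores (HDF5: one named 2-D dataset per id)
# ---------------------------------------------------------------------------

def read_embedding_store(path, ids: Sequence[str] | None = None) -> dict[str, np.ndarray]:
    path = Path(path)
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        keys = list(f.keys())
        wanted = list(ids) if ids is not None else keys
        absent = [i for i in wanted if i not in f]
        if absent:
            raise MissingIdError(f"{path}: missing embedding(s) for {absent}")
        for i in wanted:
            arr = np.asarray(f[i], dtype=np.float64)
            if arr.ndim != 2:
                raise SchemaError(f"{path}: dataset {i!r} is {arr.ndim}-D, expected 2-D")
            out[i] = arr
    return out


def write_embedding_store(matrices: dict[str, np.ndarray], path) -> None:
    with h5py.File(path, "w") as f:
        for key, mat in matrices.items():
            f.create_dataset(key, data=np.asarray(mat, dtype=np.float64))


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(triplets: Sequence[SynergyTriplet], y_hat, path,
                      sep: str = ",") -> None:
    y_hat = np.asarray(y_hat, dtype=float)
    if len(triplets) != y_hat.shape[0]:
        raise ContractError(
            f"{len(triplets)} triplets but {y_hat.shape[0]} predictions")
    df = pd.DataFrame({
        "drug_a": [t.drug_a for t in triplets],
        "drug_b": [t.drug_b for t in triplets],
        "cell_line": [t.cell_line for t in triplets],
        "y": [repr(t.y) for t in triplets],
        "y_hat": [repr(float(v)) for v in y_hat],
    })
    df.to_csv(path, sep=sep, index=False)


def read_predictions(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip",
                     dtype={"drug_a": str, "drug_b": str, "cell_line": str})
    for col in ("drug_a", "drug_b", "cell_line", "y_hat"):
        if col not in df.columns:
            raise SchemaError(f"{path}: prediction table missing column {col!r}")
    return df
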