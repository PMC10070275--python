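"""Readers and writers for gene-score matrices, label tables and predictions.

Matrices are stored genes x cells (``X in R^{G x N}``); every cell-wise
operation downstream iterates columns. Supported on-disk formats are the
10x-style Matrix Market triplet directory (``matrix.mtx`` + ``features.tsv``
+ ``barcodes.tsv``, optionally gzipped), dense delimited tables, and a flat
CSV for prediction output.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


def _as_str_array(names: Sequence[str]) -> np.ndarray:
    return np.asarray(list(names), dtype=object)


@dataclass
class GeneScoreMatrix:
    """A genes x cells non-negative score matrix with row/column names.

    Parameters
    ----------
    values : ndarray or sparse matrix, shape (n_genes, n_cells)
        Non-negative, finite gene scores.
    gene_names : sequence of str
        Unique gene identifiers, one per row (exact-string namespace; any
        symbol/Ensembl mapping is left to the caller).
    barcodes : sequence of str
        Unique cell barcodes, one per column.
    """

    values: np.ndarray | sp.spmatrix
    gene_names: np.ndarray = field()
    barcodes: np.ndarray = field()
    #: set True for transformed (e.g. standardized) matrices that are no
    #: longer raw scores and may legitimately hold negative values
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.gene_names = _as_str_array(self.gene_names)
        self.barcodes = _as_str_array(self.barcodes)
        if sp.issparse(self.values):
            self.values = self.values.tocsc()
            data = self.values.data
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValueError("values must be a 2-D genes x cells matrix")
            data = self.values
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_names):
            raise ValueError(f"{n_genes} rows but {len(self.gene_names)} gene names")
        if n_cells != len(self.barcodes):
            raise ValueError(f"{n_cells} columns but {len(self.barcodes)} barcodes")
        if data.size and not np.isfinite(data).all():
            raise ValueError("gene scores must be finite (found NaN/Inf)")
        if not self.allow_negative and data.size and data.min() < 0:
            raise ValueError("gene scores must be non-negative")
        for label, names in (("gene names", self.gene_names), ("barcodes", self.barcodes)):
            uniq, counts = np.unique(names.astype(str), return_counts=True)
            if (counts > 1).any():
                dupes = uniq[counts > 1][:5].tolist()
                raise ValueError(f"duplicate {label}: {dupes}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        """Dense float64 copy of the score matrix."""
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.array(self.values, dtype=float)


@dataclass
class LabelVector:
    """Per-cell categorical cell-type labels (barcode -> cell type)."""

    barcodes: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = _as_str_array(self.barcodes)
        self.labels = _as_str_array(self.labels)
        if len(self.labels) != len(self.barcodes):
            raise ValueError("labels and barcodes must have equal length")
        if any(lab == "" for lab in self.labels):
            raise ValueError("empty label strings are not allowed")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("at least 2 distinct cell types are required")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


# ---------------------------------------------------------------------------
# Matrix Market (10x-style) directory layout
# ---------------------------------------------------------------------------

_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")


def _find_file(directory: Path, candidates: Sequence[str], kind: str) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    # fall back to any *.mtx / *.mtx.gz for the matrix itself
    if kind == "matrix":
        hits = sorted(directory.glob("*.mtx")) + sorted(directory.glob("*.mtx.gz"))
        if hits:
            return hits[0]
    raise FormatError(f"no {kind} file among {candidates} in {directory}")


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_sidecar(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse sidecar {path}: {exc}") from exc


def read_mtx_dir(path: str | Path) -> GeneScoreMatrix:
    """Read a 10x-style Matrix Market directory into a :class:`GeneScoreMatrix`.

    The directory must contain a coordinate ``.mtx`` file plus
    ``features.tsv``/``genes.tsv`` and ``barcodes.tsv`` sidecars, any of which
    may be gzipped. Gene sidecars may have one column (name) or several
    (id, name, ...); the last column is used as the display name.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")
    mtx_path = _find_file(directory, _MTX_NAMES, "matrix")
    feat_path = _find_file(directory, _FEATURE_NAMES, "features")
    bc_path = _find_file(directory, _BARCODE_NAMES, "barcodes")

    with _open_maybe_gzip(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:
            raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}") from exc
    genes = _read_sidecar(feat_path).iloc[:, -1].to_numpy()
    barcodes = _read_sidecar(bc_path).iloc[:, 0].to_numpy()
    if mat.shape[0] != len(genes) or mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix is {mat.shape} but sidecars give {len(genes)} genes x {len(barcodes)} barcodes"
        )
    return GeneScoreMatrix(sp.csc_matrix(mat), genes, barcodes)


def write_mtx_dir(m: GeneScoreMatrix, path: str | Path) -> None:
    """Write ``m`` as a Matrix Market directory readable by :func:`read_mtx_dir`.

    Values are written at 17 significant digits so float64 scores round-trip
    bit-exactly.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    values = m.values if sp.issparse(m.values) else sp.csc_matrix(m.values)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), values, precision=17)
    pd.Series(m.gene_names).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.barcodes).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Dense delimited tables
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.name.endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")) else ","


def read_dense_table(path: str | Path, genes_in_rows: bool = True) -> GeneScoreMatrix:
    """Read a dense delimited table (CSV/TSV, optionally gzipped).

    The first column holds row names and the header row holds column names.
    With ``genes_in_rows=True`` rows are genes and columns are cells; with
    ``False`` the table is transposed after reading so the result is always
    genes x cells.
    """
    p = Path(path)
    df = pd.read_csv(p, sep=_sep_for(p), index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().to_numpy().any() and not df.isna().to_numpy().any():
        bad = np.argwhere(body.isna().to_numpy())[0]
        raise FormatError(
            f"non-numeric value at row '{df.index[bad[0]]}', column '{df.columns[bad[1]]}' in {p}"
        )
    if body.isna().to_numpy().any():
        raise FormatError(f"missing/non-numeric values in {p}")
    if not genes_in_rows:
        body = body.T
    return GeneScoreMatrix(body.to_numpy(dtype=float), body.index.to_numpy(), body.columns.to_numpy())


_HEADER_HINTS = {
    "barcode", "barcodes", "cell", "cells", "index", "cell_id",
    "celltype", "cell_type", "cell.type", "label", "labels", "type",
}


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column barcode -> cell-type table, with or without a header.

    The first row is treated as a header when either field, lower-cased,
    matches a conventional column name (barcode/cell/celltype/label/...).
    Duplicate barcodes and single-type files are rejected.
    """
    p = Path(path)
    df = pd.read_csv(p, sep=_sep_for(p), header=None, dtype=str).dropna(how="all")
    if df.shape[1] < 2:
        raise FormatError(f"label table {p} needs two columns (barcode, cell type)")
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if any(v in _HEADER_HINTS for v in first):
        df = df.iloc[1:]
    barcodes = df.iloc[:, 0].str.strip().to_numpy()
    labels = df.iloc[:, 1].str.strip().to_numpy()
    if len(np.unique(barcodes)) != len(barcodes):
        raise FormatError(f"duplicate barcodes in {p}")
    if len(np.unique(labels)) < 2:
        raise FormatError(f"label table {p} has fewer than 2 distinct cell types")
    return LabelVector(barcodes, labels)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(result, path: str | Path) -> None:
    """Write a prediction result to a flat CSV.

    Columns: barcode, predicted_celltype, first_round_celltype, entropy,
    is_anchor, then one ``prob_<celltype>`` column per class, rows in target
    barcode order. ``result`` is any object exposing ``barcodes``,
    ``final_labels``, ``first_round_labels``, ``entropy``, ``is_anchor``,
    ``proba`` and ``class_names`` (see ``tworound.PredictionResult``).
    """
    df = pd.DataFrame(
        {
            "barcode": result.barcodes,
            "predicted_celltype": result.final_labels,
            "first_round_celltype": result.first_round_labels,
            "entropy": result.entropy,
            "is_anchor": result.is_anchor,
        }
    )
    for j, name in enumerate(result.class_names):
        df[f"prob_{name}"] = result.proba[:, j]
    df.to_csv(path, index=False, float_format="%.10g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_predictions` back into a DataFrame."""
    df = pd.read_csv(path)
    df["barcode"] = df["barcode"].astype(str)
    df["is_anchor"] = df["is_anchor"].astype(bool)
    return df
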